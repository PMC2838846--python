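"""Profile hidden Markov models and log-odds bit scoring.

A :class:`ProfileHMM` is the classical match/insert/delete architecture: L
match states with position-specific emissions, L+1 insert states (insert state
k sits after match k; insert 0 precedes the model), delete states, and a
20-letter null (background) model.  All scores are log-odds in bits
(log base 2 of model versus null probability).

Two alignment modes are supported:

``glocal``
    The whole model aligns to the whole sequence: the path enters at node 0
    (begin), consumes every residue, and exits after node L.

``local``
    The model matches a subsequence.  The path may enter any match state with
    uniform probability 1/L and exit from any match state at no cost; the
    flanking residues outside the hit are emitted by the null model and
    therefore contribute exactly zero bits.  This is the mode used for
    proteome searching, where a kinase domain is a subsequence of the protein.

The Viterbi score (best single path) is the classification score throughout
the package; the forward score (sum over all paths) is provided for parity.
Both are computed in log2 space by dynamic programming, so scores stay finite
for sequences of tens of thousands of residues.

Models serialise losslessly to a versioned JSON schema (``khmm-1``); a
best-effort importer for HMMER3 ASCII files ("HMMER3/f") is included.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .proteome_io import AMINO_ACIDS, ProteinRecord

N_AA = 20
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_X_INDEX = N_AA  # extra column scored at null probability

#: order of the seven per-node transition probabilities
TRANSITION_NAMES = ("mm", "mi", "md", "im", "ii", "dm", "dd")

_PROB_TOL = 1e-9
#: floor (bits) for log2 of a zero probability; see _ScoringArrays
LOG_FLOOR = -1.0e6
MODEL_FORMAT = "khmm-1"

AlignmentMode = Literal["local", "glocal"]


@dataclass(frozen=True)
class BitScore:
    """A log2 model-vs-null odds score with the algorithm that produced it."""

    value: float
    algorithm: Literal["viterbi", "forward"]

    def __float__(self) -> float:
        return self.value


@dataclass
class ProfileHMM:
    """Position-specific probabilistic model of a protein family.

    ``transitions`` is an (L+1, 7) array with one row per node k = 0..L and
    columns ``mm, mi, md, im, ii, dm, dd``.  Row k holds the transitions that
    leave node k: M_k→M_{k+1}, M_k→I_k, M_k→D_{k+1}, I_k→M_{k+1}, I_k→I_k,
    D_k→M_{k+1}, D_k→D_{k+1}.  Node 0's match state is the begin state B; at
    row L the "next match state" is the end state E (so ``md`` must be 0 and
    ``dd`` must be 0 there).
    """

    name: str
    length: int
    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (L+1, 20)
    transitions: np.ndarray  # (L+1, 7)
    null_model: np.ndarray  # (20,)
    group: str | None = None
    alignment_mode: AlignmentMode = "local"

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.null_model = np.asarray(self.null_model, dtype=float)
        self.validate()

    @property
    def L(self) -> int:
        return self.length

    def validate(self) -> None:
        L = self.length
        if L < 1:
            raise ValueError("model length must be >= 1")
        if self.match_emissions.shape != (L, N_AA):
            raise ValueError(f"match_emissions must be ({L}, {N_AA})")
        if self.insert_emissions.shape != (L + 1, N_AA):
            raise ValueError(f"insert_emissions must be ({L + 1}, {N_AA})")
        if self.transitions.shape != (L + 1, len(TRANSITION_NAMES)):
            raise ValueError(f"transitions must be ({L + 1}, 7)")
        if self.null_model.shape != (N_AA,):
            raise ValueError("null_model must have 20 entries")
        for arr, what in (
            (self.match_emissions, "match emission"),
            (self.insert_emissions, "insert emission"),
            (self.transitions, "transition"),
            (self.null_model, "null model"),
        ):
            if np.any(arr < 0):
                raise ValueError(f"negative {what} probability")
        for label, rows in (
            ("match emission", self.match_emissions),
            ("insert emission", self.insert_emissions),
        ):
            sums = rows.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(f"{label} row {bad} sums to {sums[bad]:.6g}, not 1")
        t = self.transitions
        m_sum = t[:, 0] + t[:, 1] + t[:, 2]
        i_sum = t[:, 3] + t[:, 4]
        d_sum = t[:, 5] + t[:, 6]
        if np.any(np.abs(m_sum - 1.0) > 1e-6):
            raise ValueError("match-state transition distribution does not sum to 1")
        if np.any(np.abs(i_sum - 1.0) > 1e-6):
            raise ValueError("insert-state transition distribution does not sum to 1")
        if np.any(np.abs(d_sum - 1.0) > 1e-6):
            raise ValueError("delete-state transition distribution does not sum to 1")
        if t[L, 2] > _PROB_TOL or t[L, 6] > _PROB_TOL:
            raise ValueError("node L cannot transition to a delete state")
        if abs(self.null_model.sum() - 1.0) > 1e-6:
            raise ValueError("null model does not sum to 1")

    def with_mode(self, mode: AlignmentMode) -> "ProfileHMM":
        return replace(self, alignment_mode=mode)


# ---------------------------------------------------------------------------
# sequence encoding and log-space model arrays
# ---------------------------------------------------------------------------

def encode_sequence(sequence: str) -> np.ndarray:
    """Map residues to 0..19 (X and anything non-standard to index 20)."""
    return np.array([_AA_INDEX.get(ch, _X_INDEX) for ch in sequence], dtype=np.intp)


class _ScoringArrays:
    """Stacked log2 arrays for one or more models of equal length.

    Emission columns are log-odds (log2 e/null) with an extra all-zero column
    for X, so ambiguous residues are scored at null probability.
    """

    def __init__(self, models: Sequence[ProfileHMM]):
        lengths = {m.length for m in models}
        if len(lengths) != 1:
            raise ValueError("stacked models must share one length")
        self.L = lengths.pop()
        self.n_models = len(models)
        G, L = self.n_models, self.L
        # zero probabilities are floored at 2**LOG_FLOOR instead of -inf: an
        # astronomically penalised path can never win, yet scores stay finite
        # and the delete-chain prefix-sum trick stays NaN-free
        with np.errstate(divide="ignore"):
            me = np.stack([np.log2(m.match_emissions) - np.log2(m.null_model) for m in models])
            ie = np.stack([np.log2(m.insert_emissions) - np.log2(m.null_model) for m in models])
            t = np.stack([np.log2(np.maximum(m.transitions, 0.0)) for m in models])
        me = np.maximum(me, LOG_FLOOR)
        ie = np.maximum(ie, LOG_FLOOR)
        t = np.maximum(t, LOG_FLOOR)
        self.em = np.concatenate([me, np.zeros((G, L, 1))], axis=2)  # (G, L, 21)
        self.ie = np.concatenate([ie, np.zeros((G, L + 1, 1))], axis=2)
        (self.mm, self.mi, self.md, self.im, self.ii, self.dm, self.dd) = (
            t[:, :, k] for k in range(7)
        )
        self.entry = -math.log2(L)  # uniform local entry over match states
        # delete-chain prefix sums, constant across residues: C[:, j] = dd[1] + .. + dd[j]
        self.C = np.concatenate(
            [np.zeros((G, 1)), np.cumsum(self.dd[:, 1:L], axis=1)], axis=1
        )


def _viterbi_glocal(a: _ScoringArrays, seq: np.ndarray) -> np.ndarray:
    G, L = a.n_models, a.L
    NEG = -np.inf
    # state values after consuming i residues; index j = node
    M = np.full((G, L + 1), NEG)
    I = np.full((G, L + 1), NEG)
    D = np.full((G, L + 1), NEG)
    M[:, 0] = 0.0  # begin state
    # delete chain reachable before any emission: B -> D1 -> ... -> Dj
    D[:, 1] = M[:, 0] + a.md[:, 0]
    for j in range(2, L + 1):
        D[:, j] = D[:, j - 1] + a.dd[:, j - 1]
    for x in seq:
        newM = np.full((G, L + 1), NEG)
        cand = np.maximum(
            M[:, :-1] + a.mm[:, :-1],
            np.maximum(I[:, :-1] + a.im[:, :-1], D[:, :-1] + a.dm[:, :-1]),
        )
        newM[:, 1:] = a.em[:, :, x] + cand
        newI = a.ie[:, :, x] + np.maximum(M + a.mi, I + a.ii)
        newD = np.full((G, L + 1), NEG)
        # D_j best over M_k -> D_{k+1} -> ... -> D_j, via a running prefix max
        C = a.C
        W = newM[:, :L] + a.md[:, :L] - C
        R = np.maximum.accumulate(W, axis=1)
        newD[:, 1:] = R + C
        M, I, D = newM, newI, newD
    # exit to E from node L (D_L -> E carries probability dm[L] = 1)
    return np.maximum(
        M[:, L] + a.mm[:, L], np.maximum(I[:, L] + a.im[:, L], D[:, L] + a.dm[:, L])
    )


def _forward_glocal(a: _ScoringArrays, seq: np.ndarray) -> np.ndarray:
    G, L = a.n_models, a.L
    NEG = -np.inf
    M = np.full((G, L + 1), NEG)
    I = np.full((G, L + 1), NEG)
    D = np.full((G, L + 1), NEG)
    M[:, 0] = 0.0
    D[:, 1] = M[:, 0] + a.md[:, 0]
    for j in range(2, L + 1):
        D[:, j] = D[:, j - 1] + a.dd[:, j - 1]
    for x in seq:
        newM = np.full((G, L + 1), NEG)
        cand = np.logaddexp2(
            M[:, :-1] + a.mm[:, :-1],
            np.logaddexp2(I[:, :-1] + a.im[:, :-1], D[:, :-1] + a.dm[:, :-1]),
        )
        newM[:, 1:] = a.em[:, :, x] + cand
        newI = a.ie[:, :, x] + np.logaddexp2(M + a.mi, I + a.ii)
        newD = np.full((G, L + 1), NEG)
        C = a.C
        W = newM[:, :L] + a.md[:, :L] - C
        R = np.logaddexp2.accumulate(W, axis=1)
        newD[:, 1:] = R + C
        M, I, D = newM, newI, newD
    return np.logaddexp2(
        M[:, L] + a.mm[:, L], np.logaddexp2(I[:, L] + a.im[:, L], D[:, L] + a.dm[:, L])
    )


def _viterbi_local(a: _ScoringArrays, seq: np.ndarray) -> np.ndarray:
    """Best local hit score per model: enter any match state (cost -log2 L),
    exit from any match state free; flanks are null-scored (zero cost)."""
    G, L = a.n_models, a.L
    NEG = -np.inf
    M = np.full((G, L + 1), NEG)
    I = np.full((G, L + 1), NEG)
    D = np.full((G, L + 1), NEG)
    best = np.full(G, NEG)
    for x in seq:
        newM = np.full((G, L + 1), NEG)
        cand = np.maximum(
            M[:, :-1] + a.mm[:, :-1],
            np.maximum(I[:, :-1] + a.im[:, :-1], D[:, :-1] + a.dm[:, :-1]),
        )
        newM[:, 1:] = a.em[:, :, x] + np.maximum(cand, a.entry)
        newM[:, 1] = a.em[:, 0, x] + a.entry  # node 1 only reachable by entry
        newI = a.ie[:, :, x] + np.maximum(M + a.mi, I + a.ii)
        newI[:, 0] = NEG  # I_0 unused in local mode (no begin node)
        newD = np.full((G, L + 1), NEG)
        C = a.C
        W = newM[:, :L] + a.md[:, :L] - C
        R = np.maximum.accumulate(W, axis=1)
        newD[:, 1:] = R + C
        M, I, D = newM, newI, newD
        best = np.maximum(best, newM[:, 1:].max(axis=1))
    return best


def _forward_local(a: _ScoringArrays, seq: np.ndarray) -> np.ndarray:
    G, L = a.n_models, a.L
    NEG = -np.inf
    M = np.full((G, L + 1), NEG)
    I = np.full((G, L + 1), NEG)
    D = np.full((G, L + 1), NEG)
    total = np.full(G, NEG)
    for x in seq:
        newM = np.full((G, L + 1), NEG)
        cand = np.logaddexp2(
            M[:, :-1] + a.mm[:, :-1],
            np.logaddexp2(I[:, :-1] + a.im[:, :-1], D[:, :-1] + a.dm[:, :-1]),
        )
        with np.errstate(invalid="ignore"):
            newM[:, 1:] = a.em[:, :, x] + np.logaddexp2(cand, a.entry)
        newM[:, 1] = a.em[:, 0, x] + a.entry
        newI = a.ie[:, :, x] + np.logaddexp2(M + a.mi, I + a.ii)
        newI[:, 0] = NEG
        newD = np.full((G, L + 1), NEG)
        C = a.C
        W = newM[:, :L] + a.md[:, :L] - C
        R = np.logaddexp2.accumulate(W, axis=1)
        newD[:, 1:] = R + C
        M, I, D = newM, newI, newD
        total = np.logaddexp2(total, np.logaddexp2.reduce(newM[:, 1:], axis=1))
    return total


def _viterbi_local_traceback(hmm: ProfileHMM, seq: np.ndarray) -> tuple[float, int, int]:
    """Local Viterbi with hit envelope: returns (bits, start, end), 1-based
    inclusive coordinates of the residues inside the best-scoring hit."""
    a = _ScoringArrays([hmm])
    L = a.L
    NEG = -np.inf
    M = np.full(L + 1, NEG)
    I = np.full(L + 1, NEG)
    D = np.full(L + 1, NEG)
    sM = np.zeros(L + 1, dtype=np.intp)
    sI = np.zeros(L + 1, dtype=np.intp)
    sD = np.zeros(L + 1, dtype=np.intp)
    mm, mi, md, im, ii, dm, dd = (a.mm[0], a.mi[0], a.md[0], a.im[0], a.ii[0], a.dm[0], a.dd[0])
    em, ie = a.em[0], a.ie[0]
    best, best_start, best_end = NEG, 0, 0
    for i, x in enumerate(seq, start=1):
        prevM_shift = M[:-1]
        cands = np.stack([
            prevM_shift + mm[:-1],
            I[:-1] + im[:-1],
            D[:-1] + dm[:-1],
            np.full(L, a.entry),
        ])  # (4, L)
        starts = np.stack([sM[:-1], sI[:-1], sD[:-1], np.full(L, i, dtype=np.intp)])
        pick = np.argmax(cands, axis=0)
        cols = np.arange(L)
        newM = np.full(L + 1, NEG)
        newM[1:] = em[:, x] + cands[pick, cols]
        newM[1] = em[0, x] + a.entry
        newsM = np.zeros(L + 1, dtype=np.intp)
        newsM[1:] = starts[pick, cols]
        newsM[1] = i
        i_cands = np.stack([M + mi, I + ii])
        i_pick = np.argmax(i_cands, axis=0)
        newI = ie[:, x] + i_cands[i_pick, np.arange(L + 1)]
        newI[0] = NEG
        newsI = np.where(i_pick == 0, sM, sI)
        # delete chain with running argmax for start propagation
        C = np.concatenate([[0.0], np.cumsum(dd[1:L])])  # (L,)
        W = newM[:L] + md[:L] - C
        R = np.maximum.accumulate(W)
        idx = np.maximum.accumulate(np.where(W >= R, np.arange(L), 0))
        newD = np.full(L + 1, NEG)
        newD[1:] = R + C
        newsD = np.zeros(L + 1, dtype=np.intp)
        newsD[1:] = newsM[idx]
        M, I, D, sM, sI, sD = newM, newI, newD, newsM, newsI, newsD
        j_best = int(np.argmax(M[1:])) + 1
        if M[j_best] > best:
            best, best_start, best_end = float(M[j_best]), int(sM[j_best]), i
    return best, best_start, best_end


# ---------------------------------------------------------------------------
# public scoring API
# ---------------------------------------------------------------------------

def _as_indices(seq: ProteinRecord | str | np.ndarray) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        idx = seq
    else:
        s = seq.sequence if isinstance(seq, ProteinRecord) else seq
        idx = encode_sequence(s)
    if idx.size == 0:
        raise ValueError("cannot score an empty sequence")
    return idx


def viterbi_bit_score(
    hmm: ProfileHMM, seq: ProteinRecord | str, mode: AlignmentMode | None = None
) -> BitScore:
    """Best-path log2 odds of *seq* under *hmm* relative to the null model."""
    idx = _as_indices(seq)
    a = _ScoringArrays([hmm])
    fn = _viterbi_local if (mode or hmm.alignment_mode) == "local" else _viterbi_glocal
    return BitScore(value=float(fn(a, idx)[0]), algorithm="viterbi")


def forward_bit_score(
    hmm: ProfileHMM, seq: ProteinRecord | str, mode: AlignmentMode | None = None
) -> BitScore:
    """All-paths (log-sum-exp) log2 odds of *seq* under *hmm* vs the null."""
    idx = _as_indices(seq)
    a = _ScoringArrays([hmm])
    fn = _forward_local if (mode or hmm.alignment_mode) == "local" else _forward_glocal
    return BitScore(value=float(fn(a, idx)[0]), algorithm="forward")


def score_many(
    models: Sequence[ProfileHMM],
    seq: ProteinRecord | str,
    mode: AlignmentMode = "local",
    algorithm: Literal["viterbi", "forward"] = "viterbi",
) -> np.ndarray:
    """Score one sequence against several models in a single stacked DP.

    Models of different lengths are grouped by length internally.  Returns an
    array of bit scores aligned with *models*.
    """
    idx = _as_indices(seq)
    out = np.empty(len(models))
    by_len: dict[int, list[int]] = {}
    for i, m in enumerate(models):
        by_len.setdefault(m.length, []).append(i)
    table = {
        ("local", "viterbi"): _viterbi_local,
        ("local", "forward"): _forward_local,
        ("glocal", "viterbi"): _viterbi_glocal,
        ("glocal", "forward"): _forward_glocal,
    }
    fn = table[(mode, algorithm)]
    for _, ids in by_len.items():
        a = _ScoringArrays([models[i] for i in ids])
        out[ids] = fn(a, idx)
    return out


def _viterbi_local_batch(a: _ScoringArrays, seqs: Sequence[np.ndarray]) -> np.ndarray:
    """Local Viterbi of many sequences against a model stack at once.

    Sequences are padded to the longest; scores of finished sequences are
    frozen by masking, so padding cannot alter them.  Returns (n_seq, G).
    """
    B, G, L = len(seqs), a.n_models, a.L
    NEG = -np.inf
    lengths = np.array([s.size for s in seqs])
    n_max = int(lengths.max())
    padded = np.full((B, n_max), _X_INDEX, dtype=np.intp)
    for b, s in enumerate(seqs):
        padded[b, : s.size] = s
    M = np.full((B, G, L + 1), NEG)
    I = np.full((B, G, L + 1), NEG)
    D = np.full((B, G, L + 1), NEG)
    best = np.full((B, G), NEG)
    em = np.moveaxis(a.em, 2, 0)  # (21, G, L) so em[x] gathers per residue
    ie = np.moveaxis(a.ie, 2, 0)
    for i in range(n_max):
        x = padded[:, i]
        newM = np.full((B, G, L + 1), NEG)
        cand = np.maximum(
            M[:, :, :-1] + a.mm[:, :-1],
            np.maximum(I[:, :, :-1] + a.im[:, :-1], D[:, :, :-1] + a.dm[:, :-1]),
        )
        newM[:, :, 1:] = em[x] + np.maximum(cand, a.entry)
        newI = ie[x] + np.maximum(M + a.mi, I + a.ii)
        newI[:, :, 0] = NEG
        newD = np.full((B, G, L + 1), NEG)
        W = newM[:, :, :L] + a.md[:, :L] - a.C
        newD[:, :, 1:] = np.maximum.accumulate(W, axis=2) + a.C
        M, I, D = newM, newI, newD
        alive = lengths > i
        best[alive] = np.maximum(best[alive], newM[alive, :, 1:].max(axis=2))
    return best


def score_proteome(
    models: Sequence[ProfileHMM],
    proteins: Sequence[ProteinRecord],
    block: int = 64,
) -> np.ndarray:
    """Local Viterbi bit scores of every protein against every model,
    batched for throughput.  Returns an (n_proteins, n_models) array equal to
    stacking :func:`score_many` over the proteins.
    """
    if not proteins:
        return np.zeros((0, len(models)))
    encoded = [encode_sequence(p.sequence) for p in proteins]
    for p, e in zip(proteins, encoded):
        if e.size == 0:
            raise ValueError(f"cannot score empty sequence {p.id!r}")
    out = np.empty((len(proteins), len(models)))
    by_len: dict[int, list[int]] = {}
    for i, m in enumerate(models):
        by_len.setdefault(m.length, []).append(i)
    # sort sequences by length so padding waste inside a block stays small
    order = sorted(range(len(encoded)), key=lambda i: encoded[i].size)
    for _, mids in by_len.items():
        a = _ScoringArrays([models[i] for i in mids])
        for lo in range(0, len(order), block):
            chunk = order[lo: lo + block]
            out[np.ix_(chunk, mids)] = _viterbi_local_batch(a, [encoded[i] for i in chunk])
    return out


def viterbi_hit(hmm: ProfileHMM, seq: ProteinRecord | str) -> tuple[float, int, int]:
    """Local Viterbi score with the 1-based inclusive envelope of the hit."""
    idx = _as_indices(seq)
    return _viterbi_local_traceback(hmm, idx)


# ---------------------------------------------------------------------------
# model construction from alignments
# ---------------------------------------------------------------------------

_GAPS = set("-.")


def build_from_alignment(
    msa: Sequence[str],
    name: str = "model",
    group: str | None = None,
    match_column_rule: float = 0.5,
    pseudocount: float = 1.0,
    null_model: np.ndarray | None = None,
    alignment_mode: AlignmentMode = "local",
) -> ProfileHMM:
    """Build a profile HMM from a gapped alignment by maximum likelihood with
    Laplace-style pseudocounts.

    Columns whose gap fraction is below *match_column_rule* become match
    states; residues in non-match columns are treated as insertions.  The null
    model defaults to the alignment's overall residue frequencies (with the
    same pseudocount).
    """
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("alignment rows have unequal lengths")
    if width == 0:
        raise ValueError("alignment has zero columns")
    rows = [row.upper() for row in msa]
    n = len(rows)

    gap_frac = np.array(
        [sum(1 for r in rows if r[c] in _GAPS) / n for c in range(width)]
    )
    match_cols = [c for c in range(width) if gap_frac[c] < match_column_rule]
    L = len(match_cols)
    if L == 0:
        raise ValueError("no column qualifies as a match state under the rule")

    def _aa_idx(ch: str) -> int | None:
        if ch in _GAPS:
            return None
        return _AA_INDEX.get(ch)  # non-standard -> None, skipped in counting

    me = np.full((L, N_AA), pseudocount)
    ie = np.full((L + 1, N_AA), pseudocount)
    # transition counts per node: [mm, mi, md, im, ii, dm, dd]
    tc = np.full((L + 1, 7), pseudocount)
    tc[L, 2] = 0.0  # node L cannot enter a delete
    tc[L, 6] = 0.0
    tc[0, 5:7] = 0.0  # no delete state at node 0

    match_set = set(match_cols)
    col_to_node = {c: k + 1 for k, c in enumerate(match_cols)}

    for row in rows:
        # state walk: node 0 match state is the begin state
        prev = ("M", 0)
        for c in range(width):
            ch = row[c]
            if c in match_set:
                node = col_to_node[c]
                if ch in _GAPS:
                    state = ("D", node)
                else:
                    state = ("M", node)
                    ai = _aa_idx(ch)
                    if ai is not None:
                        me[node - 1, ai] += 1
                tc[prev[1], _trans_col(prev[0], state[0])] += 1
                prev = state
            else:
                if ch in _GAPS:
                    continue
                state = ("I", prev[1])
                ai = _aa_idx(ch)
                if ai is not None:
                    ie[prev[1], ai] += 1
                tc[prev[1], _trans_col(prev[0], state[0])] += 1
                prev = state
        tc[prev[1], _trans_col(prev[0], "M")] += 1  # exit to E counts as ->M

    me /= me.sum(axis=1, keepdims=True)
    ie /= ie.sum(axis=1, keepdims=True)

    t = np.zeros_like(tc)
    t[:, 0:3] = tc[:, 0:3] / tc[:, 0:3].sum(axis=1, keepdims=True)
    t[:, 3:5] = tc[:, 3:5] / tc[:, 3:5].sum(axis=1, keepdims=True)
    d_sum = tc[:, 5:7].sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        t[:, 5:7] = np.where(d_sum > 0, tc[:, 5:7] / np.maximum(d_sum, 1e-300), 0.0)
    t[0, 5] = 1.0  # unused distributions pinned to a valid point mass
    t[L, 5] = 1.0
    t[L, 6] = 0.0

    if null_model is None:
        counts = np.full(N_AA, pseudocount)
        for row in rows:
            for ch in row:
                ai = _aa_idx(ch)
                if ai is not None:
                    counts[ai] += 1
        null = counts / counts.sum()
    else:
        null = np.asarray(null_model, dtype=float)

    return ProfileHMM(
        name=name,
        group=group,
        length=L,
        match_emissions=me,
        insert_emissions=ie,
        transitions=t,
        null_model=null,
        alignment_mode=alignment_mode,
    )


def _trans_col(a: str, b: str) -> int:
    return {
        ("M", "M"): 0, ("M", "I"): 1, ("M", "D"): 2,
        ("I", "M"): 3, ("I", "I"): 4,
        ("D", "M"): 5, ("D", "D"): 6,
    }[(a, b)]


# ---------------------------------------------------------------------------
# model serialisation (khmm-1 JSON) and HMMER3 import
# ---------------------------------------------------------------------------

def write_model(hmm: ProfileHMM, path: str | Path) -> None:
    doc = {
        "format": MODEL_FORMAT,
        "name": hmm.name,
        "group": hmm.group,
        "length": hmm.length,
        "alphabet": AMINO_ACIDS,
        "alignment_mode": hmm.alignment_mode,
        "match_emissions": hmm.match_emissions.tolist(),
        "insert_emissions": hmm.insert_emissions.tolist(),
        "transitions": {
            nm: hmm.transitions[:, k].tolist() for k, nm in enumerate(TRANSITION_NAMES)
        },
        "null_model": hmm.null_model.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_model(path: str | Path) -> ProfileHMM:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path}: not a {MODEL_FORMAT} model file")
    if doc.get("alphabet") != AMINO_ACIDS:
        raise ValueError(f"{path}: unsupported alphabet")
    L = int(doc["length"])
    trans = np.column_stack([np.asarray(doc["transitions"][nm], dtype=float)
                             for nm in TRANSITION_NAMES])
    return ProfileHMM(
        name=doc["name"],
        group=doc.get("group"),
        length=L,
        match_emissions=np.asarray(doc["match_emissions"], dtype=float),
        insert_emissions=np.asarray(doc["insert_emissions"], dtype=float),
        transitions=trans,
        null_model=np.asarray(doc["null_model"], dtype=float),
        alignment_mode=doc.get("alignment_mode", "local"),
    )


def read_hmmer3(path: str | Path, warnings: list[str] | None = None) -> ProfileHMM:
    """Best-effort import of a HMMER3 ASCII amino-acid model ("HMMER3/f").

    Emission and transition fields are mapped onto :class:`ProfileHMM`;
    HMMER-specific extras (E-value calibration stats, MAP/RF annotation, ...)
    are skipped and noted in *warnings*.  The import is not bit-exact with
    HMMER's own scoring conventions.
    """
    if warnings is None:
        warnings = []
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("HMMER3"):
        raise ValueError(f"{path}: not a HMMER3 ASCII file")
    name, L, alpha = "imported", None, None
    i = 1
    while i < len(lines) and not lines[i].startswith("HMM "):
        key = lines[i].split(maxsplit=1)
        if key:
            if key[0] == "NAME" and len(key) > 1:
                name = key[1].strip()
            elif key[0] == "LENG":
                L = int(key[1])
            elif key[0] == "ALPH":
                alpha = key[1].strip().lower()
            elif key[0] in {"STATS", "MAP", "RF", "MM", "CONS", "CS", "GA", "TC", "NC"}:
                warnings.append(f"ignored header field {key[0]}")
        i += 1
    if L is None:
        raise ValueError(f"{path}: missing LENG")
    if alpha != "amino":
        raise ValueError(f"{path}: only amino alphabet supported")
    header = lines[i].split()
    order = header[1:]
    if order[:N_AA] != list(AMINO_ACIDS):
        raise ValueError(f"{path}: unexpected emission column order")
    i += 2  # skip the m->m ... transition label line

    def _probs(tokens: Sequence[str]) -> np.ndarray:
        return np.array([0.0 if t == "*" else math.exp(-float(t)) for t in tokens])

    me = np.zeros((L, N_AA))
    ie = np.zeros((L + 1, N_AA))
    trans = np.zeros((L + 1, 7))
    if lines[i].split()[0] == "COMPO":
        warnings.append("COMPO line used as null model")
        null = _probs(lines[i].split()[1:N_AA + 1])
        null = null / null.sum()
        i += 1
    else:
        null = np.full(N_AA, 1.0 / N_AA)
        warnings.append("no COMPO line; uniform null model assumed")
    ie[0] = _probs(lines[i].split()[:N_AA]); i += 1
    trans[0] = _probs(lines[i].split()[:7]); i += 1
    for k in range(1, L + 1):
        tok = lines[i].split()
        if int(tok[0]) != k:
            raise ValueError(f"{path}: node {k} out of order")
        me[k - 1] = _probs(tok[1:N_AA + 1]); i += 1
        ie[k] = _probs(lines[i].split()[:N_AA]); i += 1
        trans[k] = _probs(lines[i].split()[:7]); i += 1
    # renormalise (HMMER rounds to 5 decimals) and pin node-L delete rows
    me /= me.sum(axis=1, keepdims=True)
    ie /= ie.sum(axis=1, keepdims=True)
    trans[L, 2] = 0.0
    trans[L, 5:7] = (1.0, 0.0)
    trans[0, 5:7] = (1.0, 0.0)
    trans[:, 0:3] /= trans[:, 0:3].sum(axis=1, keepdims=True)
    trans[:, 3:5] /= trans[:, 3:5].sum(axis=1, keepdims=True)
    dsum = trans[:, 5:7].sum(axis=1, keepdims=True)
    trans[:, 5:7] = np.where(dsum > 0, trans[:, 5:7] / np.maximum(dsum, 1e-300), 0.0)
    return ProfileHMM(
        name=name, group=None, length=L, match_emissions=me, insert_emissions=ie,
        transitions=trans, null_model=null, alignment_mode="local",
    )
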