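"""Local alignment, read QC, consensus and error-rate profiling.

The aligner is a plain Smith-Waterman dynamic program with the platform's
scoring (+2 match, -2 substitution, -1 for a deletion or insertion in the
read) and deterministic tie-breaking (diagonal > up > left).  Reads here
are short (~10 nt) flow-sequencing reads aligned against 70-nt template
references, so the quadratic DP is ample; the inner kernel is jitted so
that runs with 10^5-10^6 reads stay fast.

Consensus calling follows the most-frequent-symbol rule per reference
position over {A, C, G, T, deletion}; identity is the fraction of covered
reference positions whose consensus symbol equals the reference base.
For pileups, each local alignment is extended diagonally (gap-free) to
the full read so that substitutions in the first or last read bases -
which an optimal local alignment soft-clips - are still tallied; raw
scores and spans are never altered by this extension.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .simcore import BASES, ReadSet, ReferenceSet, encode

DEL_SYMBOL = 4  # index of the deletion symbol in tally arrays
SYMBOLS = "ACGT-"


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring: positive match reward, non-positive penalties."""

    match: int = 2
    mismatch: int = -2
    deletion_gap: int = -1  # gap consuming the reference (deletion in read)
    insertion_gap: int = -1  # gap consuming the read (insertion in read)

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.deletion_gap > 0 or self.insertion_gap > 0:
            raise ValueError("penalties must be <= 0")


@dataclass(frozen=True)
class QCParams:
    min_length: int = 5
    min_multiplicity: int = 4

    def __post_init__(self):
        if self.min_length < 1 or self.min_multiplicity < 1:
            raise ValueError("QC parameters must be >= 1")

    @property
    def alignability_floor(self) -> int:
        """Best-score floor for rule 3: less than a perfect min_length-mer."""
        return 2 * self.min_length


@dataclass
class Alignment:
    """One optimal local alignment of a read against a reference.

    ``ops`` is a string over '=' (match), 'X' (substitution), 'D'
    (deletion in the read: reference consumed) and 'I' (insertion in the
    read: read consumed).  Spans are 0-based half-open.
    """

    read: str
    reference_id: str
    score: int
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    ops: str

    def op_counts(self) -> Counter:
        return Counter(self.ops)


@dataclass
class FilterReport:
    n_input: int
    removed_short: int
    removed_rare: int
    removed_unalignable: int

    @property
    def n_pass(self) -> int:
        return self.n_input - self.removed_short - self.removed_rare - self.removed_unalignable


@dataclass
class ConsensusResult:
    reference_id: str
    tallies: np.ndarray  # (5, L) counts over A,C,G,T,deletion
    consensus: str  # '-' marks a deletion consensus, 'N' an uncovered position
    identity: float
    coverage: np.ndarray  # (L,)


@dataclass
class ErrorProfile:
    """Positional error rates plus two aggregate views.

    ``overall_*`` follows the unweighted mean-over-positions definition;
    ``pooled_*`` divides total error events by the total number of
    profiled pileup entries (``n_profiled``), which is the estimator the
    binomial sampling theory applies to.
    """

    reference_id: str
    substitution_rate: np.ndarray  # per position; NaN where uncovered
    deletion_rate: np.ndarray
    overall_substitution: float
    overall_deletion: float
    pooled_substitution: float
    pooled_deletion: float
    n_profiled: int  # pileup entries behind the pooled rates
    insertion_per_base: float
    n_aligned_bases: int


@dataclass
class AccuracyCurve:
    depths: List[int]
    mean_identity: List[float]
    n_reps: int
    seed: int
    mode: str = "position"


# ---------------------------------------------------------------------------
# Smith-Waterman kernel
# ---------------------------------------------------------------------------


@njit(cache=False)
def _sw_kernel(a, b, match, mismatch, gap_read, gap_ref):
    """Full DP matrix with pointers; returns (P, best, bi, bj).

    Pointer codes: 0 stop, 1 diagonal, 2 up (consume read), 3 left
    (consume reference).  Ties break diagonal > up > left; the best cell
    is the first maximum in row-major order.
    """
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    P = np.zeros((m + 1, n + 1), dtype=np.int8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            p = 1
            up = H[i - 1, j] + gap_read
            if up > h:
                h = up
                p = 2
            left = H[i, j - 1] + gap_ref
            if left > h:
                h = left
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            P[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return P, best, bi, bj


@njit(cache=False)
def _sw_score(a, b, match, mismatch, gap_read, gap_ref):
    """Score-only Smith-Waterman (two-row DP)."""
    m = a.shape[0]
    n = b.shape[0]
    prev = np.zeros(n + 1, dtype=np.int64)
    cur = np.zeros(n + 1, dtype=np.int64)
    best = 0
    for i in range(1, m + 1):
        cur[0] = 0
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = prev[j - 1] + s
            up = prev[j] + gap_read
            if up > h:
                h = up
            left = cur[j - 1] + gap_ref
            if left > h:
                h = left
            if h < 0:
                h = 0
            cur[j] = h
            if h > best:
                best = h
        prev, cur = cur, prev
    return best


def smith_waterman(read: str, reference: str, scoring: ScoringScheme = ScoringScheme(),
                   reference_id: str = "ref") -> Alignment:
    """Optimal local alignment with deterministic traceback.

    An empty read (or an all-negative scoring situation) yields the empty
    alignment with score 0.
    """
    a = encode(read)
    b = encode(reference)
    if len(a) == 0 or len(b) == 0:
        return Alignment(read, reference_id, 0, 0, 0, 0, 0, "")
    P, best, bi, bj = _sw_kernel(
        a, b, scoring.match, scoring.mismatch, scoring.insertion_gap, scoring.deletion_gap
    )
    if best <= 0:
        return Alignment(read, reference_id, 0, 0, 0, 0, 0, "")
    ops: List[str] = []
    i, j = bi, bj
    while P[i, j] != 0:
        p = P[i, j]
        if p == 1:
            ops.append("=" if a[i - 1] == b[j - 1] else "X")
            i -= 1
            j -= 1
        elif p == 2:
            ops.append("I")
            i -= 1
        else:
            ops.append("D")
            j -= 1
    ops.reverse()
    return Alignment(
        read=read,
        reference_id=reference_id,
        score=int(best),
        read_start=i,
        read_end=bi,
        ref_start=j,
        ref_end=bj,
        ops="".join(ops),
    )


def sw_score(read: str, reference: str, scoring: ScoringScheme = ScoringScheme()) -> int:
    """Best local-alignment score only (no traceback)."""
    a = encode(read)
    b = encode(reference)
    if len(a) == 0 or len(b) == 0:
        return 0
    return int(
        _sw_score(a, b, scoring.match, scoring.mismatch, scoring.insertion_gap,
                  scoring.deletion_gap)
    )


def score_matrix(
    seqs: Sequence[str], references: Mapping[str, str], scoring: ScoringScheme = ScoringScheme()
) -> np.ndarray:
    """(n_seqs, n_refs) best local-alignment scores, reference order preserved."""
    ref_codes = [encode(r) for r in references.values()]
    out = np.zeros((len(seqs), len(ref_codes)), dtype=np.int64)
    for i, s in enumerate(seqs):
        a = encode(s)
        if len(a) == 0:
            continue
        for j, b in enumerate(ref_codes):
            out[i, j] = _sw_score(
                a, b, scoring.match, scoring.mismatch, scoring.insertion_gap,
                scoring.deletion_gap
            )
    return out


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def _references_dict(refs) -> Dict[str, str]:
    if isinstance(refs, ReferenceSet):
        out = dict(refs.wild_refs())
        for name, seq in refs.mutant_refs().items():
            out[f"{name}__mut"] = seq
        return out
    return dict(refs)


def qc_filter(
    reads: ReadSet,
    refs,
    params: QCParams = QCParams(),
    scoring: ScoringScheme = ScoringScheme(),
) -> Tuple[ReadSet, FilterReport]:
    """Three-rule read QC, applied in order.

    1. drop reads shorter than ``min_length``;
    2. drop reads whose exact base string occurs fewer than
       ``min_multiplicity`` times among the remaining reads;
    3. drop reads whose best local-alignment score against every
       reference falls below the alignability floor (a perfect
       ``min_length``-mer).
    """
    n0 = len(reads)
    keep = np.array([len(s) >= params.min_length for s in reads.seqs], dtype=bool)
    removed_short = int(n0 - keep.sum())

    counts = Counter(s for s, k in zip(reads.seqs, keep) if k)
    rare = np.array(
        [k and counts[s] < params.min_multiplicity for s, k in zip(reads.seqs, keep)],
        dtype=bool,
    )
    keep &= ~rare
    removed_rare = int(rare.sum())

    references = _references_dict(refs)
    unique = sorted({s for s, k in zip(reads.seqs, keep) if k})
    if unique:
        best = score_matrix(unique, references, scoring).max(axis=1)
        alignable = {s: b >= params.alignability_floor for s, b in zip(unique, best)}
    else:
        alignable = {}
    unal = np.array(
        [k and not alignable[s] for s, k in zip(reads.seqs, keep)], dtype=bool
    )
    keep &= ~unal
    removed_unalignable = int(unal.sum())

    report = FilterReport(n0, removed_short, removed_rare, removed_unalignable)
    return reads.subset(keep), report


# ---------------------------------------------------------------------------
# Read -> reference assignment and pileups
# ---------------------------------------------------------------------------


@dataclass
class TemplatePileup:
    """Unique alignments (with multiplicities) of reads assigned to one reference."""

    reference_id: str
    reference: str
    alignments: List[Alignment]
    weights: np.ndarray  # read multiplicity per unique alignment

    @property
    def n_reads(self) -> int:
        return int(self.weights.sum())


PROFILING_SCORING = ScoringScheme(match=2, mismatch=-2, deletion_gap=-4, insertion_gap=-4)
"""Gap-averse scoring used to assign and realign reads for error profiling.

Under the platform scoring a gap (-1) plus a shifted match (+2) beats a
substitution (-2) whenever the wrong base coincides with an adjacent
reference base, so the aligner systematically re-explains substitutions
as indels and inflates cross-template background scores.  A gap penalty
of -4 makes that reinterpretation an exact tie, which the diagonal-first
tie-break resolves to the substitution, while genuine indels (which have
no substitution explanation) are still aligned as gaps.
"""


def assign_reads(
    seqs: Sequence[str],
    references: Mapping[str, str],
    scoring: ScoringScheme = ScoringScheme(),
    alignment_scoring: Optional[ScoringScheme] = None,
) -> Dict[str, TemplatePileup]:
    """Assign each read to its best-scoring reference and align it.

    Reads whose best score ties across two or more references are of
    ambiguous origin and are dropped from all pileups.  Alignment work is
    deduplicated over identical read strings.  ``alignment_scoring``
    optionally realigns each read under a different scheme once its
    reference is decided (assignment always uses ``scoring``); pass
    :data:`PROFILING_SCORING` when the pileup feeds error-rate profiling.
    """
    names = list(references.keys())
    counts = Counter(seqs)
    unique = sorted(counts)
    scores = score_matrix(unique, references, scoring)
    traceback_scoring = alignment_scoring or scoring
    pileups: Dict[str, List[Tuple[Alignment, int]]] = {n: [] for n in names}
    for row, seq in enumerate(unique):
        s = scores[row]
        best = s.max()
        if best <= 0 or (s == best).sum() > 1:
            continue
        name = names[int(np.argmax(s))]
        aln = smith_waterman(seq, references[name], traceback_scoring, reference_id=name)
        pileups[name].append((aln, counts[seq]))
    out = {}
    for name in names:
        alns = [a for a, _ in pileups[name]]
        w = np.array([c for _, c in pileups[name]], dtype=np.int64)
        out[name] = TemplatePileup(name, references[name], alns, w)
    return out


def _column_contributions(
    aln: Alignment, reference: str, extend: bool = True, trim_tail: int = 0,
    trim_head: int = 0, extension_limit: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray, int, int]:
    """Reference columns touched by one alignment.

    Returns (positions, symbols, n_read_bases, n_insertions) where
    symbols are base codes 0..3 or DEL_SYMBOL.  With ``extend`` the
    alignment is continued diagonally to the read ends (no gaps) so
    boundary substitutions enter the pileup.  ``trim_tail`` and
    ``trim_head`` drop the last/first reference columns of the (extended)
    alignment - evidence at a read's boundaries, where a local aligner
    cannot distinguish a boundary substitution from a gap-plus-shifted-
    match reinterpretation.  ``extension_limit`` caps how many bases the
    diagonal extension may add at each end (a long soft clip usually
    hides gaps, and extending it diagonally would fabricate mismatches).
    """
    positions: List[int] = []
    symbols: List[int] = []
    n_ins = 0
    rs, fs = aln.read_start, aln.ref_start
    if extend:
        lead = min(rs, fs)
        if extension_limit is not None:
            lead = min(lead, extension_limit)
        for k in range(lead, 0, -1):
            positions.append(fs - k)
            symbols.append("ACGT".index(aln.read[rs - k]))
    i, j = rs, fs
    for op in aln.ops:
        if op in "=X":
            positions.append(j)
            symbols.append("ACGT".index(aln.read[i]))
            i += 1
            j += 1
        elif op == "D":
            positions.append(j)
            symbols.append(DEL_SYMBOL)
            j += 1
        else:  # I
            n_ins += 1
            i += 1
    if extend:
        trail = min(len(aln.read) - aln.read_end, len(reference) - aln.ref_end)
        if extension_limit is not None:
            trail = min(trail, extension_limit)
        for k in range(trail):
            positions.append(aln.ref_end + k)
            symbols.append("ACGT".index(aln.read[aln.read_end + k]))
    if trim_tail:
        positions = positions[: max(len(positions) - trim_tail, 0)]
        symbols = symbols[: len(positions)]
    if trim_head:
        positions = positions[trim_head:]
        symbols = symbols[trim_head:]
    n_read_bases = len(aln.read) if extend else (aln.read_end - aln.read_start)
    return (
        np.array(positions, dtype=np.int64),
        np.array(symbols, dtype=np.int64),
        n_read_bases,
        n_ins,
    )


def pileup_tallies(
    alignments: Sequence[Alignment],
    reference: str,
    weights: Optional[np.ndarray] = None,
    extend: bool = False,
) -> np.ndarray:
    """(5, L) tallies over {A, C, G, T, deletion} from aligned columns."""
    L = len(reference)
    tallies = np.zeros((5, L), dtype=np.int64)
    if weights is None:
        weights = np.ones(len(alignments), dtype=np.int64)
    for aln, w in zip(alignments, weights):
        pos, sym, _, _ = _column_contributions(aln, reference, extend=extend)
        np.add.at(tallies, (sym, pos), w)
    return tallies


def consensus_from_tallies(
    tallies: np.ndarray,
    reference: str,
    tie_to_reference: bool = True,
    min_coverage: int = 1,
) -> ConsensusResult:
    """Majority-vote consensus from a tally matrix.

    Ties break toward the reference base when ``tie_to_reference`` (the
    default), else strictly lexicographically over 'ACGT-'.  Positions
    covered by fewer than ``min_coverage`` reads are marked 'N' (no
    call) and excluded from identity.
    """
    L = len(reference)
    coverage = tallies.sum(axis=0)
    cons = []
    correct = 0
    covered = 0
    ref_codes = encode(reference)
    for p in range(L):
        if coverage[p] < max(min_coverage, 1):
            cons.append("N")
            continue
        covered += 1
        col = tallies[:, p]
        best = col.max()
        winners = np.flatnonzero(col == best)
        if tie_to_reference and ref_codes[p] in winners:
            sym = int(ref_codes[p])
        else:
            sym = int(winners[0])
        cons.append(SYMBOLS[sym])
        if sym == ref_codes[p]:
            correct += 1
    identity = correct / covered if covered else float("nan")
    return ConsensusResult(
        reference_id="", tallies=tallies, consensus="".join(cons),
        identity=identity, coverage=coverage,
    )


def consensus(
    alignments: Sequence[Alignment],
    reference: str,
    weights: Optional[np.ndarray] = None,
    tie_to_reference: bool = True,
    extend: bool = False,
    min_coverage_fraction: float = 0.05,
    reference_id: str = "ref",
) -> ConsensusResult:
    """Per-position majority consensus of reads aligned to one reference.

    By default only optimally aligned columns enter the pileup; with
    ``extend`` each alignment is continued diagonally to the read ends
    first (see module docstring).  Consensus is called only at positions
    with coverage of at least ``min_coverage_fraction`` of the maximum
    position coverage: beyond the flow protocol's extension horizon the
    sole coverage comes from deletion-bearing reads, which carry no
    majority information (set the fraction to 0 to call every covered
    position).
    """
    if len(alignments) == 0:
        raise ValueError("consensus requires at least one alignment")
    tallies = pileup_tallies(alignments, reference, weights, extend=extend)
    floor = int(np.ceil(min_coverage_fraction * tallies.sum(axis=0).max()))
    res = consensus_from_tallies(tallies, reference, tie_to_reference, min_coverage=floor)
    res.reference_id = reference_id
    return res


def error_profile(
    alignments: Sequence[Alignment],
    reference: str,
    weights: Optional[np.ndarray] = None,
    extend: bool = True,
    trim_tail: int = 3,
    trim_head: int = 2,
    extension_limit: Optional[int] = 2,
    min_coverage_fraction: float = 0.1,
    reference_id: str = "ref",
) -> ErrorProfile:
    """Per-position substitution and deletion rates.

    A position's rate is the number of covering reads disagreeing with
    the reference (by substitution, resp. deletion) divided by its
    coverage; overall rates are means over covered positions.  Insertions
    do not occupy reference columns and are reported as a separate
    per-aligned-read-base rate.

    Alignments are extended to the full read by default so boundary
    errors are not censored by local-alignment soft clipping, and each
    read's last ``trim_tail`` and first ``trim_head`` reference columns
    are excluded from the tallies (numerator and denominator alike): at
    a read's boundary the optimal local alignment turns a substitution
    into a gap plus a shifted match whenever the wrong base coincides
    with an adjacent reference base, so boundary evidence systematically
    under-reports substitutions; rates are therefore estimated from
    read-interior evidence only.  Positions whose coverage falls below
    ``min_coverage_fraction`` of the maximum position coverage are
    excluded from the overall means (their rate stays reported per
    position): past the flow protocol's extension horizon only stray
    insertion bases provide coverage, and a handful of such reads would
    swamp an unweighted per-position mean.
    """
    L = len(reference)
    if weights is None:
        weights = np.ones(len(alignments), dtype=np.int64)
    tallies = np.zeros((5, L), dtype=np.int64)
    n_bases = 0
    n_ins = 0
    for aln, w in zip(alignments, weights):
        pos, sym, nb, ni = _column_contributions(aln, reference, extend=extend,
                                                 trim_tail=trim_tail, trim_head=trim_head,
                                                 extension_limit=extension_limit)
        np.add.at(tallies, (sym, pos), w)
        n_bases += nb * int(w)
        n_ins += ni * int(w)
    coverage = tallies.sum(axis=0)
    ref_codes = encode(reference)
    sub = np.full(L, np.nan)
    dele = np.full(L, np.nan)
    for p in range(L):
        if coverage[p] == 0:
            continue
        col = tallies[:, p]
        n_sub = col[:4].sum() - col[ref_codes[p]]
        sub[p] = n_sub / coverage[p]
        dele[p] = col[DEL_SYMBOL] / coverage[p]
    cov_mask = coverage >= max(1, min_coverage_fraction * coverage.max())
    n_profiled = int(coverage[cov_mask].sum())
    n_sub = int(
        sum(tallies[:4, p].sum() - tallies[ref_codes[p], p] for p in np.flatnonzero(cov_mask))
    )
    n_del = int(tallies[DEL_SYMBOL, cov_mask].sum())
    return ErrorProfile(
        reference_id=reference_id,
        substitution_rate=sub,
        deletion_rate=dele,
        overall_substitution=float(np.nanmean(sub[cov_mask])) if cov_mask.any() else float("nan"),
        overall_deletion=float(np.nanmean(dele[cov_mask])) if cov_mask.any() else float("nan"),
        pooled_substitution=n_sub / n_profiled if n_profiled else float("nan"),
        pooled_deletion=n_del / n_profiled if n_profiled else float("nan"),
        n_profiled=n_profiled,
        insertion_per_base=n_ins / n_bases if n_bases else float("nan"),
        n_aligned_bases=n_bases,
    )


# ---------------------------------------------------------------------------
# Sampling-subsampling accuracy curve
# ---------------------------------------------------------------------------


def _tallies_with_insertions(
    alignments: Sequence[Alignment],
    reference: str,
    weights: Optional[np.ndarray] = None,
    extend: bool = True,
) -> np.ndarray:
    """(10, L) tallies: rows 0-4 as in :func:`pileup_tallies` for reads
    without an insertion at the column's junction, rows 5-9 for reads
    carrying one (an I op immediately before consuming that column)."""
    L = len(reference)
    tallies = np.zeros((10, L), dtype=np.int64)
    if weights is None:
        weights = np.ones(len(alignments), dtype=np.int64)
    for aln, w in zip(alignments, weights):
        pos, sym, _, _ = _column_contributions(aln, reference, extend=extend)
        ins_at = set()
        j = aln.ref_start
        for op in aln.ops:
            if op == "I":
                ins_at.add(j)
            else:
                j += 1
        if len(pos):
            flags = np.array([5 if int(p) in ins_at else 0 for p in pos])
            np.add.at(tallies, (sym + flags, pos), w)
    return tallies


def subsample_accuracy(
    alignments: Sequence[Alignment],
    reference: str,
    depths: Sequence[int],
    n_reps: int = 50,
    seed: int = 0,
    weights: Optional[np.ndarray] = None,
    mode: str = "position",
    tie_to_reference: bool = True,
    min_coverage_fraction: float = 0.05,
    extend: bool = True,
    boundary_trim: int = 1,
) -> AccuracyCurve:
    """Consensus accuracy as a function of coverage depth.

    ``mode='position'`` (default) draws exactly ``d`` pileup entries
    without replacement at every reference position with coverage >= d
    and recomputes the majority symbol - coverage depth d means each base
    is covered d times.  ``mode='reads'`` instead draws whole reads to a
    mean coverage of d.  Identity per replicate is averaged over
    replicates for each depth.  Positions below ``min_coverage_fraction``
    of the maximum coverage are excluded, as in :func:`consensus`, and so
    are the first and last ``boundary_trim`` eligible positions: the
    template start and the flow protocol's extension horizon see only
    read-boundary evidence, where errors are structurally censored
    (a deletion of the first base or of a read's final base leaves no
    alignment trace), so including them would overstate accuracy at low
    depth.  Tallies use full-read extension by default so the depth-1
    point reflects the raw per-base error process rather than the
    soft-clipped alignment cores.

    A consensus built from few reads inherits their inserted bases, so a
    position is also scored wrong when more than half of the drawn reads
    carry an insertion at that junction; at full depth insertions never
    reach a majority and the rule is inert.
    """
    rng = np.random.default_rng(seed)
    tallies = _tallies_with_insertions(alignments, reference, weights, extend=extend)
    coverage = tallies.sum(axis=0)
    floor = int(np.ceil(min_coverage_fraction * coverage.max()))
    ref_codes = encode(reference)
    mean_identity = []
    if mode == "position":
        if max(depths) > coverage.max():
            raise ValueError("requested depth exceeds available coverage")
        for d in depths:
            eligible = np.flatnonzero(coverage >= max(d, floor))
            if boundary_trim and len(eligible) > 2 * boundary_trim + 1:
                eligible = eligible[boundary_trim:-boundary_trim]
            idents = []
            for _ in range(n_reps):
                correct = 0
                covered = 0
                for p in eligible:
                    col10 = rng.multivariate_hypergeometric(tallies[:, p], d)
                    col = col10[:5] + col10[5:]
                    n_ins = int(col10[5:].sum())
                    best = col.max()
                    winners = np.flatnonzero(col == best)
                    if tie_to_reference and ref_codes[p] in winners:
                        sym = int(ref_codes[p])
                    else:
                        sym = int(winners[0])
                    covered += 1
                    if sym == ref_codes[p] and 2 * n_ins <= d:
                        correct += 1
                idents.append(correct / covered)
            mean_identity.append(float(np.mean(idents)))
    elif mode == "reads":
        if weights is None:
            weights = np.ones(len(alignments), dtype=np.int64)
        # expand unique alignments to per-read index list
        expanded = np.repeat(np.arange(len(alignments)), weights.astype(int))
        mean_cov = float(coverage[coverage > 0].mean())
        n_total = len(expanded)
        for d in depths:
            n_draw = int(round(n_total * d / mean_cov))
            if n_draw > n_total:
                raise ValueError("requested depth exceeds available coverage")
            idents = []
            for _ in range(n_reps):
                pick = rng.choice(expanded, size=n_draw, replace=False)
                sub_w = np.bincount(pick, minlength=len(alignments))
                t = pileup_tallies(alignments, reference, sub_w, extend=extend)
                res = consensus_from_tallies(t, reference, tie_to_reference)
                idents.append(res.identity)
            mean_identity.append(float(np.mean(idents)))
    else:
        raise ValueError("mode must be 'position' or 'reads'")
    return AccuracyCurve(
        depths=list(depths), mean_identity=mean_identity, n_reps=n_reps, seed=seed, mode=mode
    )
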