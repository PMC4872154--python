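"""Low-frequency mutation detection by dual-reference alignment.

Each read is aligned to both the wild-type and the mutant reference of
its template; the higher score decides its origin (a tie goes to mutant
by default, which makes the estimated mutant frequency an upper bound -
sequencing errors and non-discriminating reads inflate it, never deflate
it).  Per-field-of-view mutant frequencies are compared against a pure
wild-type control with a two-sample Student t-test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .alignqc import QCParams, ScoringScheme, qc_filter, score_matrix, smith_waterman
from .simcore import (
    ErrorModel,
    FlowProtocol,
    ReadSet,
    ReferenceSet,
    simulate_readset,
)

POOLED = "__pooled__"


@dataclass(frozen=True)
class OriginCall:
    read_id: str
    template: str
    score_wild: int
    score_mutant: int
    label: str  # "wild" | "mutant" | "dropped"


@dataclass
class MixtureResult:
    """Per-template, per-batch wild/mutant call tallies.

    Batches are fields of view - the replicate unit for the significance
    test.  ``mutant_counts[t, b]`` and ``total_counts[t, b]`` hold the
    mutant calls and classified reads for template ``t`` in batch ``b``.
    """

    template_names: List[str]
    batch_ids: np.ndarray
    mutant_counts: np.ndarray  # (n_templates, n_batches)
    total_counts: np.ndarray  # (n_templates, n_batches)

    @property
    def n_effective_reads(self) -> int:
        return int(self.total_counts.sum())

    def frequency(self, template: Optional[str] = None) -> float:
        """Pooled mutant-read frequency (NaN when no reads classified)."""
        if template is None:
            m, t = self.mutant_counts.sum(), self.total_counts.sum()
        else:
            i = self.template_names.index(template)
            m, t = self.mutant_counts[i].sum(), self.total_counts[i].sum()
        return m / t if t else float("nan")

    def batch_frequencies(self, template: Optional[str] = None) -> np.ndarray:
        """Per-batch mutant frequency, pooled over templates by default."""
        if template is None:
            m = self.mutant_counts.sum(axis=0)
            t = self.total_counts.sum(axis=0)
        else:
            i = self.template_names.index(template)
            m, t = self.mutant_counts[i], self.total_counts[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(t > 0, m / np.maximum(t, 1), np.nan)


@dataclass
class TTestResult:
    template: str
    t: float
    p: float


@dataclass
class DetectionScanResult:
    fractions: List[float]
    p_values: List[float]
    frequencies: List[float]  # measured pooled mutant frequency per tested fraction
    control_frequency: float
    alpha: float
    smallest_significant: Optional[float]


# ---------------------------------------------------------------------------
# Read classification
# ---------------------------------------------------------------------------


def classify_read(
    read: str,
    wild_ref: str,
    mutant_ref: str,
    scoring: ScoringScheme = ScoringScheme(),
    tie_policy: str = "mutant",
    read_id: str = "read",
    template: str = "template",
) -> OriginCall:
    """Dual-reference origin call for a single read.

    Wild if the wild-type score is strictly higher; otherwise mutant
    (``tie_policy='mutant'``, the default) or dropped
    (``tie_policy='drop'``).
    """
    sw = smith_waterman(read, wild_ref, scoring).score
    sm = smith_waterman(read, mutant_ref, scoring).score
    if sw > sm:
        label = "wild"
    elif sm > sw:
        label = "mutant"
    else:
        label = "mutant" if tie_policy == "mutant" else "dropped"
    return OriginCall(read_id, template, sw, sm, label)


def _variant_locus(refs: ReferenceSet, t_idx: int) -> Tuple[int, int]:
    """Half-open wild-reference interval that discriminates the variant."""
    v = refs.templates[t_idx].variant
    if v.kind == "point":
        return v.position, v.position + 1
    return v.position, v.position + v.del_length


def classify_readset(
    reads: ReadSet,
    refs: ReferenceSet,
    scoring: ScoringScheme = ScoringScheme(),
    tie_policy: str = "mutant",
    span_filter: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised origin calls for a whole read set.

    Returns (template_assignment, label) per read; template -1 and label
    -1 mark reads dropped for ambiguous template origin (equal best score
    on two templates) or by the span filter.  Labels: 0 wild, 1 mutant.
    Alignment work is deduplicated over identical read strings.

    With ``span_filter`` a read must overlap the variant locus of its
    assigned template (judged on its wild-reference alignment span) to be
    counted; non-spanning reads carry no signal and, under the literal
    tie-to-mutant rule, only inflate the mutant frequency.
    """
    names = refs.names
    n_t = len(names)
    references: Dict[str, str] = {}
    for t in refs.templates:
        references[t.name] = t.wild
        references[f"{t.name}__mut"] = t.mutant
    counts = Counter(reads.seqs)
    unique = sorted(counts)
    scores = score_matrix(unique, references, scoring)  # (n_unique, 2*n_t)
    wild_s = scores[:, 0::2]
    mut_s = scores[:, 1::2]
    per_template = np.maximum(wild_s, mut_s)

    u_assign = np.full(len(unique), -1, dtype=np.int64)
    u_label = np.full(len(unique), -1, dtype=np.int8)
    for row, seq in enumerate(unique):
        s = per_template[row]
        best = s.max()
        if best <= 0 or (s == best).sum() > 1:
            continue
        t_idx = int(np.argmax(s))
        if span_filter:
            aln = smith_waterman(seq, refs.templates[t_idx].wild, scoring)
            lo, hi = _variant_locus(refs, t_idx)
            if aln.ref_end <= lo or aln.ref_start >= hi:
                continue
        sw, sm = wild_s[row, t_idx], mut_s[row, t_idx]
        if sw > sm:
            lab = 0
        elif sm > sw:
            lab = 1
        else:
            if tie_policy == "drop":
                continue
            lab = 1
        u_assign[row] = t_idx
        u_label[row] = lab

    index = {s: i for i, s in enumerate(unique)}
    rows = np.array([index[s] for s in reads.seqs], dtype=np.int64)
    return u_assign[rows], u_label[rows]


def mixture_frequencies(
    reads: ReadSet,
    refs: ReferenceSet,
    scoring: ScoringScheme = ScoringScheme(),
    tie_policy: str = "mutant",
    span_filter: bool = False,
) -> MixtureResult:
    """Mutant-read frequency per template and per field of view.

    Expects QC-filtered reads.  Reads with ambiguous template origin are
    excluded; the pooled frequency is mutant calls over all classified
    reads.
    """
    assign, label = classify_readset(reads, refs, scoring, tie_policy, span_filter)
    batch_ids = np.unique(reads.batch)
    b_index = {b: i for i, b in enumerate(batch_ids)}
    n_t = len(refs.templates)
    mutant = np.zeros((n_t, len(batch_ids)), dtype=np.int64)
    total = np.zeros((n_t, len(batch_ids)), dtype=np.int64)
    keep = assign >= 0
    for t_idx, b, lab in zip(assign[keep], reads.batch[keep], label[keep]):
        bi = b_index[int(b)]
        total[t_idx, bi] += 1
        mutant[t_idx, bi] += int(lab == 1)
    return MixtureResult(
        template_names=list(refs.names),
        batch_ids=batch_ids,
        mutant_counts=mutant,
        total_counts=total,
    )


# ---------------------------------------------------------------------------
# Significance testing
# ---------------------------------------------------------------------------


def significance_test(
    mixture: MixtureResult,
    control: MixtureResult,
    equal_var: bool = True,
    per_template: bool = True,
) -> Dict[str, TTestResult]:
    """Two-sample two-tailed Student t-test on per-batch mutant frequencies.

    Classic equal-variance form by default (``equal_var=False`` gives
    Welch).  Returns one result per template plus a pooled test under the
    key ``POOLED``.
    """
    if len(mixture.batch_ids) < 2 or len(control.batch_ids) < 2:
        raise ValueError(
            "significance_test needs >=2 batches per group; simulate more fields of view"
        )
    out: Dict[str, TTestResult] = {}
    keys = list(mixture.template_names) if per_template else []
    for key in keys + [POOLED]:
        template = None if key == POOLED else key
        a = mixture.batch_frequencies(template)
        b = control.batch_frequencies(template)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            out[key] = TTestResult(key, float("nan"), float("nan"))
            continue
        if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0) and np.isclose(a.mean(), b.mean()):
            out[key] = TTestResult(key, 0.0, 1.0)  # identical constant groups
            continue
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        out[key] = TTestResult(key, float(t), float(p))
    return out


def detection_limit_scan(
    fractions: Sequence[float],
    refs: ReferenceSet,
    n_reads_per_group: int = 200_000,
    n_batches: int = 300,
    protocol: FlowProtocol = FlowProtocol(),
    errors: ErrorModel = ErrorModel(),
    scoring: ScoringScheme = ScoringScheme(),
    qc: QCParams = QCParams(),
    alpha: float = 0.05,
    seed: int = 0,
    tie_policy: str = "mutant",
    span_filter: bool = False,
) -> DetectionScanResult:
    """Simulate mixtures over a grid of mutant fractions and test each.

    For every fraction a full read set is simulated (mutant fraction
    applied to all templates), QC-filtered and classified; its per-batch
    pooled mutant frequencies are t-tested against a pure wild-type
    control simulated under identical conditions.  Reports the smallest
    fraction with p < alpha (None when nothing is significant).
    """
    fractions = sorted(fractions, reverse=True)
    rng = np.random.default_rng(seed)

    def run(frac: float) -> MixtureResult:
        rs = simulate_readset(
            refs,
            (1.0 - frac, frac),
            n_reads_per_group,
            protocol,
            errors,
            seed=int(rng.integers(2**31)),
            n_batches=n_batches,
        )
        rs, _ = qc_filter(rs, refs, qc, scoring)
        return mixture_frequencies(rs, refs, scoring, tie_policy, span_filter)

    control = run(0.0)
    p_values: List[float] = []
    freqs: List[float] = []
    smallest: Optional[float] = None
    for frac in fractions:
        mix = run(frac)
        res = significance_test(mix, control, per_template=False)[POOLED]
        p_values.append(res.p)
        freqs.append(mix.frequency())
        if res.p < alpha and mix.frequency() > control.frequency():
            smallest = frac
    return DetectionScanResult(
        fractions=list(fractions),
        p_values=p_values,
        frequencies=freqs,
        control_frequency=control.frequency(),
        alpha=alpha,
        smallest_significant=smallest,
    )
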