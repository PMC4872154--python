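"""Read-level simulator for single-molecule targeted flow sequencing.

Generates reference/variant template sets with capture-probe metadata,
places molecules in a field of view, and simulates per-cycle single-base
incorporation under a substitution/deletion/insertion error model.  The
image-free fast path (:func:`simulate_readset`) produces reads directly;
the same event tables also drive the TIRF image renderer in
:mod:`smtseq.imagesim`.

Conventions
-----------
Templates are stored in *read space*: the stored 70-mer is the sequence of
bases the instrument reports, read from position 0.  The capture probe's
50-nt specific region is the reverse complement of template positions
20..69 (the probe anchors sequencing just upstream, so reads start at
position 0).  Cycle indices are 1-based in reports; the flowed base at
cycle ``c`` is ``flow_order[(c - 1) % 4]``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGT", "TGCA")

# EventTable outcome codes
EVT_NONE = 0
EVT_CORRECT = 1
EVT_WRONG = 2
EVT_MISSED = 3
EVT_SPURIOUS = 4

EVENT_NAMES = {
    EVT_NONE: "none",
    EVT_CORRECT: "incorporated_correct",
    EVT_WRONG: "incorporated_wrong",
    EVT_MISSED: "missed",
    EVT_SPURIOUS: "spurious",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Base string -> int8 codes (A=0, C=1, G=2, T=3)."""
    try:
        return np.array([_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"non-ACGT character in sequence: {exc}") from None


def decode(codes: Sequence[int]) -> str:
    return "".join(BASES[c] for c in codes)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantSpec:
    """A point mutation or short deletion applied to a wild-type template.

    ``position`` is a 0-based offset into the wild-type template; for
    deletions ``del_length`` bases starting at ``position`` are removed.
    """

    name: str
    kind: str  # "point" | "deletion"
    position: int
    alt_base: Optional[str] = None
    del_length: Optional[int] = None

    def __post_init__(self):
        if self.kind not in ("point", "deletion"):
            raise ValueError(f"{self.name}: kind must be 'point' or 'deletion'")
        if self.kind == "point":
            if self.alt_base not in BASES:
                raise ValueError(f"{self.name}: point variant needs alt_base in ACGT")
        else:
            if not self.del_length or not (1 <= self.del_length <= 30):
                raise ValueError(f"{self.name}: del_length must be in 1..30")

    def apply(self, wild: str) -> str:
        if self.kind == "point":
            if self.position >= len(wild):
                raise ValueError(f"{self.name}: position {self.position} out of range")
            if wild[self.position] == self.alt_base:
                raise ValueError(f"{self.name}: alt_base equals reference base")
            return wild[: self.position] + self.alt_base + wild[self.position + 1 :]
        if self.position + self.del_length > len(wild):
            raise ValueError(f"{self.name}: deletion runs past template end")
        return wild[: self.position] + wild[self.position + self.del_length :]


@dataclass(frozen=True)
class TemplateRecord:
    name: str
    wild: str
    mutant: str
    variant: VariantSpec


@dataclass
class ReferenceSet:
    """Wild-type and mutant 70-nt templates plus capture probes.

    The simulation ground truth: reads are (error-corrupted) prefixes of
    the wild or mutant template strings.
    """

    templates: List[TemplateRecord]
    probes: List[Tuple[str, str]]
    seed: int

    def __post_init__(self):
        for t in self.templates:
            if len(t.wild) != TEMPLATE_LENGTH:
                raise ValueError(f"{t.name}: wild-type template must be {TEMPLATE_LENGTH} nt")
            if t.variant.apply(t.wild) != t.mutant:
                raise ValueError(f"{t.name}: mutant string does not match its variant spec")
        for name, seq in self.probes:
            if len(seq) != PROBE_LENGTH:
                raise ValueError(f"{name}: probe must be {PROBE_LENGTH} nt")

    @property
    def names(self) -> List[str]:
        return [t.name for t in self.templates]

    def sequence(self, template_index: int, origin: int) -> str:
        """origin 0 = wild, 1 = mutant."""
        t = self.templates[template_index]
        return t.mutant if origin else t.wild

    def wild_refs(self) -> Dict[str, str]:
        return {t.name: t.wild for t in self.templates}

    def mutant_refs(self) -> Dict[str, str]:
        return {t.name: t.mutant for t in self.templates}


TEMPLATE_LENGTH = 70
PROBE_LENGTH = 60
PROBE_SPECIFIC_LENGTH = 50
PROBE_LINKER = "T" * 10


@dataclass(frozen=True)
class ProbeReport:
    gc_fraction: float
    tm: float
    passes: bool


@dataclass(frozen=True)
class FlowProtocol:
    """Cyclic single-terminator flow order and number of cycles."""

    flow_order: Tuple[str, str, str, str] = ("G", "C", "T", "A")
    n_cycles: int = 25

    def __post_init__(self):
        if sorted(self.flow_order) != list(BASES):
            raise ValueError("flow_order must be a permutation of A,C,G,T")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    def flow_base(self, cycle: int) -> str:
        """Base flowed at 1-based cycle index."""
        return self.flow_order[(cycle - 1) % len(self.flow_order)]

    def flow_codes(self) -> np.ndarray:
        return np.array(
            [_CODE[self.flow_base(c)] for c in range(1, self.n_cycles + 1)], dtype=np.int8
        )


@dataclass(frozen=True)
class ErrorModel:
    """Per-incorporation error probabilities.

    p_sub
        probability a due incorporation records a wrong base.
    p_del
        probability a due incorporation is missed (dark); the template
        base is skipped permanently, i.e. a deletion in the read.
    p_ins
        probability per non-due cycle of a spurious recorded event
        (insertion in the read).
    """

    p_sub: float = 0.0052
    p_del: float = 0.040
    p_ins: float = 0.005

    def __post_init__(self):
        for p in (self.p_sub, self.p_del, self.p_ins):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error probabilities must lie in [0, 1]")
        if self.p_sub + self.p_del + self.p_ins >= 1.0:
            raise ValueError("p_sub + p_del + p_ins must be < 1")


@dataclass(frozen=True)
class FieldGeometry:
    """Field-of-view geometry and surface occupancy statistics."""

    fov_width: float = 54.6  # um
    fov_height: float = 54.6  # um
    pixel_count: Tuple[int, int] = (512, 512)
    density: float = 0.75  # molecules / um^2
    frac_single: float = 0.38
    frac_pair: float = 0.36
    frac_cluster: float = 0.26
    site_jitter_px: float = 0.6  # spread of co-located molecules within a site

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")
        total = self.frac_single + self.frac_pair + self.frac_cluster
        if abs(total - 1.0) > 1e-9:
            raise ValueError("occupancy fractions must sum to 1")

    @property
    def area(self) -> float:
        return self.fov_width * self.fov_height

    @property
    def pixels_per_um(self) -> float:
        return self.pixel_count[0] / self.fov_width


@dataclass
class MoleculeSet:
    """Per-molecule surface placement.

    Molecules sharing a site index are co-located (aggregated) and emit
    summed fluorescence in the image path.  ``origin`` is 0 for wild-type
    and 1 for mutant molecules.
    """

    x: np.ndarray  # pixels, continuous
    y: np.ndarray
    template_index: np.ndarray
    origin: np.ndarray
    site_index: np.ndarray
    site_occupancy: np.ndarray  # occupancy of the molecule's site
    field_id: int = 0

    @property
    def n_molecules(self) -> int:
        return len(self.x)

    @property
    def n_sites(self) -> int:
        return 0 if self.n_molecules == 0 else int(self.site_index.max()) + 1

    def site_positions(self) -> np.ndarray:
        """(n_sites, 2) array of mean molecule position (x, y) per site."""
        n = self.n_sites
        counts = np.bincount(self.site_index, minlength=n).astype(float)
        out = np.zeros((n, 2))
        out[:, 0] = np.bincount(self.site_index, weights=self.x, minlength=n) / counts
        out[:, 1] = np.bincount(self.site_index, weights=self.y, minlength=n) / counts
        return out


@dataclass
class EventTable:
    """Per-molecule, per-cycle incorporation outcomes.

    ``outcome[i, c]`` is one of the EVT_* codes for molecule ``i`` at
    1-based cycle ``c + 1``; ``recorded[i, c]`` is the recorded base code
    (0..3) or -1 when no base was recorded.
    """

    outcome: np.ndarray  # (n_mol, n_cycles) int8
    recorded: np.ndarray  # (n_mol, n_cycles) int8
    protocol: FlowProtocol

    @property
    def n_molecules(self) -> int:
        return self.outcome.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.outcome.shape[1]

    def incorporated(self) -> np.ndarray:
        """Boolean (n_mol, n_cycles): a base was recorded (signal visible)."""
        return self.recorded >= 0


@dataclass
class ReadSet:
    """Decoded reads with provenance.

    ``batch`` assigns each read to a field of view (the replicate unit for
    mutant-frequency statistics).
    """

    ids: List[str]
    seqs: List[str]
    template_index: np.ndarray
    origin: np.ndarray
    batch: np.ndarray
    provenance: str = "simulated"

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("read ids must be unique")

    def __len__(self) -> int:
        return len(self.seqs)

    def subset(self, mask: np.ndarray) -> "ReadSet":
        idx = np.flatnonzero(mask)
        return ReadSet(
            ids=[self.ids[i] for i in idx],
            seqs=[self.seqs[i] for i in idx],
            template_index=self.template_index[idx],
            origin=self.origin[idx],
            batch=self.batch[idx],
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------


def default_variant_specs() -> List[VariantSpec]:
    """Six point variants and two deletions (15 nt and 21 nt).

    Emulates a drug-response panel of eight mutation sites: six point
    mutations and the two short exon-19-style deletions (5 and 7 codons).
    Positions sit within the first ten template bases so that ~10-nt reads
    span every variant; alt bases are resolved against the generated
    wild-type sequence at build time (``alt_base`` here is a placeholder
    replaced by :func:`make_references`).
    """
    points = [
        VariantSpec("EGFR_G719A", "point", 3, "A"),
        VariantSpec("EGFR_T790M", "point", 4, "A"),
        VariantSpec("EGFR_L858R", "point", 5, "A"),
        VariantSpec("KRAS_G12S", "point", 6, "A"),
        VariantSpec("KRAS_G13D", "point", 7, "A"),
        VariantSpec("BRAF_V600E", "point", 8, "A"),
    ]
    deletions = [
        VariantSpec("EGFR_dE746_A750", "deletion", 3, del_length=15),
        VariantSpec("EGFR_dE747_A753", "deletion", 3, del_length=21),
    ]
    return points + deletions


_HEAD_LENGTH = 16


def _random_template(rng: np.random.Generator) -> str:
    """Random 70-mer with a low-complexity-free sequenced head.

    The first 16 bases (the region short reads actually cover) avoid
    homopolymers and period-2/3 tandem repeats: a repeated base stalls
    the 4-base flow cycle for a full extra round, and short tandem
    repeats make deletion placement ambiguous in local alignment - the
    same low-complexity exclusions probe-design software applies.
    """
    head = [int(rng.integers(4))]
    while len(head) < _HEAD_LENGTH:
        b = int(rng.integers(4))
        if b == head[-1]:
            continue
        if len(head) >= 3 and b == head[-2] and head[-1] == head[-3]:
            continue  # would continue an ABAB pattern
        if (
            len(head) >= 5
            and b == head[-3]
            and head[-1] == head[-4]
            and head[-2] == head[-5]
        ):
            continue  # would continue an ABCABC pattern
        head.append(b)
    tail = rng.integers(0, 4, size=TEMPLATE_LENGTH - _HEAD_LENGTH)
    return decode(head) + decode(tail)


def make_references(
    n_templates: int = 8,
    variant_specs: Optional[Sequence[VariantSpec]] = None,
    seed: int = 0,
) -> ReferenceSet:
    """Build a seeded synthetic reference panel.

    One wild-type 70-mer per variant spec (cycled if ``n_templates``
    exceeds the number of specs), each paired with the mutant string
    obtained by applying the spec.  Point-variant alt bases are chosen as
    a fixed substitution of the wild base (A->C, C->G, G->T, T->A) so that
    alt always differs from the reference.  Template prefixes (first 8 nt)
    are kept distinct across templates so short reads map unambiguously.
    """
    if n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    specs = list(variant_specs) if variant_specs is not None else default_variant_specs()
    if len(specs) < n_templates:
        specs = [
            dataclasses.replace(specs[i % len(specs)], name=f"{specs[i % len(specs)].name}_{i}")
            for i in range(n_templates)
        ]
    specs = specs[:n_templates]

    rng = np.random.default_rng(seed)
    sub_of = {"A": "C", "C": "G", "G": "T", "T": "A"}
    templates: List[TemplateRecord] = []
    probes: List[Tuple[str, str]] = []
    seen_prefixes: set = set()
    for spec in specs:
        if spec.kind == "point" and spec.position >= TEMPLATE_LENGTH:
            raise ValueError(f"{spec.name}: variant position out of range for 70-nt template")
        if spec.kind == "deletion" and spec.position + spec.del_length > TEMPLATE_LENGTH:
            raise ValueError(f"{spec.name}: deletion out of range for 70-nt template")
        while True:
            wild = _random_template(rng)
            if wild[:8] not in seen_prefixes:
                break
        seen_prefixes.add(wild[:8])
        if spec.kind == "point":
            spec = dataclasses.replace(spec, alt_base=sub_of[wild[spec.position]])
        mutant = spec.apply(wild)
        templates.append(TemplateRecord(spec.name, wild, mutant, spec))
        probe_seq = reverse_complement(wild[20:TEMPLATE_LENGTH]) + PROBE_LINKER
        probes.append((f"probe_{spec.name}", probe_seq))
    return ReferenceSet(templates=templates, probes=probes, seed=seed)


# ---------------------------------------------------------------------------
# Probe checks
# ---------------------------------------------------------------------------

GC_MIN, GC_MAX = 0.20, 0.80
TM_MIN = 65.0


def melting_tm(seq: str) -> float:
    """Basic GC-fraction melting temperature: 64.9 + 41*(nGC - 16.4)/L (degC)."""
    n_gc = seq.count("G") + seq.count("C")
    return 64.9 + 41.0 * (n_gc - 16.4) / len(seq)


def check_probe(probe: str) -> ProbeReport:
    """GC-content and melting-temperature screen for a capture probe.

    Passes iff GC fraction lies in [0.20, 0.80] and Tm exceeds 65 degC.
    """
    if not probe or any(b not in BASES for b in probe):
        raise ValueError("probe must be a non-empty string over A,C,G,T")
    gc = (probe.count("G") + probe.count("C")) / len(probe)
    tm = melting_tm(probe)
    passes = (GC_MIN <= gc <= GC_MAX) and tm > TM_MIN
    return ProbeReport(gc_fraction=gc, tm=tm, passes=passes)


# ---------------------------------------------------------------------------
# Molecule placement
# ---------------------------------------------------------------------------


def _normalize_mixture(
    refs: ReferenceSet, mixture
) -> Dict[int, Tuple[float, float]]:
    if isinstance(mixture, tuple):
        mixture = {t.name: mixture for t in refs.templates}
    out = {}
    for i, t in enumerate(refs.templates):
        wf, mf = mixture.get(t.name, (1.0, 0.0))
        if abs(wf + mf - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions for {t.name} must sum to 1")
        out[i] = (wf, mf)
    return out


def place_molecules(
    refs: ReferenceSet,
    geometry: FieldGeometry,
    mixture: Mapping[str, Tuple[float, float]] | Tuple[float, float] = (1.0, 0.0),
    seed: int = 0,
    field_id: int = 0,
    n_sites: Optional[int] = None,
) -> MoleculeSet:
    """Scatter molecules over a field of view.

    The number of occupied sites is Poisson with mean density x area
    (unless ``n_sites`` is forced); each site holds 1, 2 or 3 molecules
    drawn from the (single, pair, cluster) occupancy fractions.  Templates
    are assigned uniformly and wild/mutant origin labels i.i.d. from the
    per-template mixture.  Molecules sharing a site are scattered around
    the site centre with an isotropic ``site_jitter_px`` spread - closer
    than the diffraction limit, but not coincident.
    """
    rng = np.random.default_rng(seed)
    mix = _normalize_mixture(refs, mixture)
    if n_sites is None:
        n_sites = int(rng.poisson(geometry.density * geometry.area))
    occ = rng.choice(
        [1, 2, 3],
        size=n_sites,
        p=[geometry.frac_single, geometry.frac_pair, geometry.frac_cluster],
    )
    w, h = geometry.pixel_count
    sx = rng.uniform(0, w, size=n_sites)
    sy = rng.uniform(0, h, size=n_sites)
    site_index = np.repeat(np.arange(n_sites), occ)
    n_mol = len(site_index)
    jitter = np.where(
        np.repeat(occ, occ) > 1,
        geometry.site_jitter_px,
        0.0,
    )
    mx = np.clip(sx[site_index] + rng.normal(0, 1, n_mol) * jitter, 0, w - 1e-9)
    my = np.clip(sy[site_index] + rng.normal(0, 1, n_mol) * jitter, 0, h - 1e-9)
    template_index = rng.integers(0, len(refs.templates), size=n_mol).astype(np.int32)
    origin = np.zeros(n_mol, dtype=np.int8)
    for t_idx, (wf, mf) in mix.items():
        sel = template_index == t_idx
        origin[sel] = (rng.random(int(sel.sum())) < mf).astype(np.int8)
    return MoleculeSet(
        x=mx,
        y=my,
        template_index=template_index,
        origin=origin,
        site_index=site_index,
        site_occupancy=occ[site_index],
        field_id=field_id,
    )


# ---------------------------------------------------------------------------
# Event simulation
# ---------------------------------------------------------------------------


def simulate_events(
    molecules: MoleculeSet,
    refs: ReferenceSet,
    protocol: FlowProtocol,
    errors: ErrorModel = ErrorModel(),
    seed: int = 0,
) -> EventTable:
    """Run the per-cycle incorporation process for every molecule.

    At a cycle whose flowed base equals the molecule's next unextended
    template base (a *due* cycle) the outcome is correct incorporation
    with probability 1 - p_sub - p_del, a wrong recorded base with p_sub,
    or a missed (dark) incorporation with p_del; the template pointer
    advances in all three cases, so a miss is a permanent skip.  At a
    non-due cycle a spurious event is recorded with probability p_ins.
    Vectorized over molecules; deterministic per seed.
    """
    if molecules.template_index.size and molecules.template_index.max() >= len(refs.templates):
        raise ValueError("molecule references a template not present in the ReferenceSet")
    rng = np.random.default_rng(seed)
    n_mol = molecules.n_molecules
    n_cyc = protocol.n_cycles
    outcome = np.zeros((n_mol, n_cyc), dtype=np.int8)
    recorded = np.full((n_mol, n_cyc), -1, dtype=np.int8)
    flow = protocol.flow_codes()

    # group molecules sharing an identical sequence (template, origin)
    key = molecules.template_index.astype(np.int64) * 2 + molecules.origin
    for k in np.unique(key):
        rows = np.flatnonzero(key == k)
        seq = encode(refs.sequence(int(k) // 2, int(k) % 2))
        seq_padded = np.concatenate([seq, [-2]])  # sentinel: exhausted template
        ptr = np.zeros(len(rows), dtype=np.int64)
        for c in range(n_cyc):
            nxt = seq_padded[np.minimum(ptr, len(seq))]
            due = nxt == flow[c]
            u = rng.random(len(rows))
            # due outcomes
            correct = due & (u < 1.0 - errors.p_sub - errors.p_del)
            wrong = due & ~correct & (u < 1.0 - errors.p_del)
            missed = due & ~correct & ~wrong
            spurious = ~due & (u < errors.p_ins)
            outcome[rows[correct], c] = EVT_CORRECT
            outcome[rows[wrong], c] = EVT_WRONG
            outcome[rows[missed], c] = EVT_MISSED
            outcome[rows[spurious], c] = EVT_SPURIOUS
            recorded[rows[correct], c] = flow[c]
            recorded[rows[spurious], c] = flow[c]
            if wrong.any():
                # wrong base: uniform over the three non-flow bases
                offs = rng.integers(1, 4, size=int(wrong.sum()))
                recorded[rows[wrong], c] = (flow[c] + offs) % 4
            ptr[due] += 1
    return EventTable(outcome=outcome, recorded=recorded, protocol=protocol)


def events_to_reads(
    events: EventTable,
    molecules: Optional[MoleculeSet] = None,
    batch: Optional[np.ndarray] = None,
) -> ReadSet:
    """Decode each molecule's event row into a read.

    The read is the concatenation, in cycle order, of the recorded base at
    every incorporation (correct or wrong) and spurious event; missed
    events contribute nothing.
    """
    n = events.n_molecules
    seqs = []
    rec = events.recorded
    for i in range(n):
        row = rec[i]
        seqs.append(decode(row[row >= 0]))
    if molecules is not None:
        fid = molecules.field_id
        ids = [f"f{fid}_m{i}" for i in range(n)]
        tmpl = molecules.template_index.copy()
        orig = molecules.origin.copy()
        b = np.full(n, fid, dtype=np.int32)
    else:
        ids = [f"m{i}" for i in range(n)]
        tmpl = np.full(n, -1, dtype=np.int32)
        orig = np.zeros(n, dtype=np.int8)
        b = np.zeros(n, dtype=np.int32)
    if batch is not None:
        b = np.asarray(batch, dtype=np.int32)
    return ReadSet(ids=ids, seqs=seqs, template_index=tmpl, origin=orig, batch=b)


def simulate_readset(
    refs: ReferenceSet,
    mixture: Mapping[str, Tuple[float, float]] | Tuple[float, float],
    n_reads: int,
    protocol: FlowProtocol = FlowProtocol(),
    errors: ErrorModel = ErrorModel(),
    seed: int = 0,
    n_batches: int = 1,
) -> ReadSet:
    """Fast read-level simulation bypassing imaging.

    ``n_reads`` molecules are assigned templates uniformly and origins
    from the mixture, sequenced through the flow protocol, and decoded.
    Reads are split contiguously into ``n_batches`` fields of view.
    """
    rng = np.random.default_rng(seed)
    mix = _normalize_mixture(refs, mixture)
    template_index = rng.integers(0, len(refs.templates), size=n_reads).astype(np.int32)
    origin = np.zeros(n_reads, dtype=np.int8)
    for t_idx, (_, mf) in mix.items():
        sel = template_index == t_idx
        origin[sel] = (rng.random(int(sel.sum())) < mf).astype(np.int8)
    molecules = MoleculeSet(
        x=np.zeros(n_reads),
        y=np.zeros(n_reads),
        template_index=template_index,
        origin=origin,
        site_index=np.arange(n_reads),
        site_occupancy=np.ones(n_reads, dtype=np.int64),
    )
    events = simulate_events(molecules, refs, protocol, errors, seed=int(rng.integers(2**31)))
    batch = (np.arange(n_reads) * n_batches) // max(n_reads, 1)
    batch = np.minimum(batch, n_batches - 1).astype(np.int32)
    reads = events_to_reads(events, molecules, batch=batch)
    return reads


def noise_free_extension(template: str, protocol: FlowProtocol) -> str:
    """Prefix of ``template`` incorporated in ``n_cycles`` error-free flows."""
    ptr = 0
    out = []
    for c in range(1, protocol.n_cycles + 1):
        if ptr < len(template) and protocol.flow_base(c) == template[ptr]:
            out.append(template[ptr])
            ptr += 1
    return "".join(out)
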