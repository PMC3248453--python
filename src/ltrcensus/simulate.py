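"""Synthetic fungal genomes with implanted LTR retrotransposons and ground truth.

The generator emulates the element architectures seen in fungal genomes:
Ty1/Copia elements (pol order AP-INT-RT-RH), Ty3/Gypsy elements (pol order
AP-RT-RH-INT) and chromoviruses (Gypsy with a chromodomain appended after
the integrase). Implanted copies can be left intact or degraded by point
mutations (optionally biased towards creating in-frame stop codons, a
caricature of RIP-like genome defense), indels, 5'/3' truncation, collapse
to a solo LTR, or nesting inside a previously implanted element.

Every implanted copy is recorded as a :class:`GroundTruthRecord`, so the
detector, classifier and clustering stages can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from . import seedbank
from .io import write_fasta, write_gff3

__all__ = [
    "ElementTemplate",
    "DegradationParams",
    "GroundTruthRecord",
    "SimulationConfig",
    "build_element_template",
    "default_templates",
    "render_element",
    "degrade_sequence",
    "implant_elements",
    "write_ground_truth",
]

COPIA_LAYOUT = ("GAG", "AP", "INT", "RT", "RH")
GYPSY_LAYOUT = ("GAG", "AP", "RT", "RH", "INT")

#: generic pol-domain name -> scoring-profile name, per superfamily
PROFILE_FOR = {
    "Copia": {"GAG": "GAG", "AP": "AP_RVP", "INT": "INT_rve",
              "RT": "RT_RVT2", "RH": "RH_LTR"},
    "Gypsy": {"GAG": "GAG", "AP": "AP_RVP2", "INT": "INT_rve",
              "RT": "RT_RVT1", "RH": "RH_LTR", "CHROMO": "CHROMO"},
}

STOP_CODONS = ("TAA", "TAG", "TGA")
_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]

# codons per amino acid, stops excluded
_CODONS_FOR_AA: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _CODONS_FOR_AA.setdefault(aa, []).append(codon)
for _aa in _CODONS_FOR_AA:
    _CODONS_FOR_AA[_aa].sort()

_NON_STOP_CODONS = sorted({c for codons in _CODONS_FOR_AA.values() for c in codons})


@dataclass(frozen=True)
class ElementTemplate:
    """Blueprint of one LTR retrotransposon lineage."""

    template_id: str
    superfamily: str  # "Copia" | "Gypsy"
    chromoviral: bool
    ltr_seq: str
    internal_seq: str
    #: ordered (generic domain name, start, end) in internal 0-based half-open nt
    domain_layout: tuple[tuple[str, int, int], ...]
    tsd_len: int

    def __post_init__(self) -> None:
        if self.superfamily not in ("Copia", "Gypsy"):
            raise ValueError(f"unknown superfamily {self.superfamily!r}")
        if self.chromoviral and self.superfamily != "Gypsy":
            raise ValueError("chromoviral templates must be Ty3/Gypsy")
        if not 100 <= len(self.ltr_seq) <= 600:
            raise ValueError("LTR length must be in [100, 600] nt")
        if not 3000 <= len(self.internal_seq) <= 8000:
            raise ValueError("internal region must be 3-8 knt")
        if not 4 <= self.tsd_len <= 6:
            raise ValueError("TSD length must be 4-6 nt")

    @property
    def length(self) -> int:
        return 2 * len(self.ltr_seq) + len(self.internal_seq)

    def profile_name(self, domain: str) -> str:
        return PROFILE_FOR[self.superfamily][domain]

    def layout_in_element_coords(self) -> list[tuple[str, int, int]]:
        off = len(self.ltr_seq)
        return [(d, s + off, e + off) for d, s, e in self.domain_layout]


@dataclass(frozen=True)
class DegradationParams:
    """Per-copy degradation model.

    ``point_rate`` is substitutions per site; with probability ``stop_bias``
    a substitution hitting a codon is redirected within that codon to create
    an in-frame stop (TAA/TAG/TGA) when a single change can do so.
    ``domain_rate_multipliers`` scales the substitution rate inside named
    domains of the internal ORF; the default doubles the aspartic-protease
    rate, reflecting the protease being the fastest-evolving pol domain.
    """

    point_rate: float = 0.0
    indel_rate: float = 0.0
    stop_bias: float = 0.0
    truncate_prob: float = 0.0
    solo_ltr_prob: float = 0.0
    nest_prob: float = 0.0
    domain_rate_multipliers: dict[str, float] = field(
        default_factory=lambda: {"AP": 2.0})

    def __post_init__(self) -> None:
        for name in ("point_rate", "indel_rate", "stop_bias",
                     "truncate_prob", "solo_ltr_prob", "nest_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    @classmethod
    def realistic(cls) -> "DegradationParams":
        """A degraded-population preset (most real copies are remnants)."""
        return cls(point_rate=0.03, indel_rate=0.002, stop_bias=0.3,
                   truncate_prob=0.3, solo_ltr_prob=0.15, nest_prob=0.05)


@dataclass
class GroundTruthRecord:
    contig: str
    start: int  # 0-based half-open, element proper (TSD excluded)
    end: int
    template_id: str
    state: str  # intact | degraded | truncated | solo_ltr | nested
    strand: str  # "+" | "-"
    n_point_mutations: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty or inverted ground-truth interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimulationConfig:
    background_len: int = 1_000_000
    gc_content: float = 0.48
    copies_per_template: int = 10
    templates: tuple[ElementTemplate, ...] = ()
    degradation: DegradationParams = field(default_factory=DegradationParams)
    seed: int = 0
    contig_name: str = "chr1"
    random_strand: bool = True


# ---------------------------------------------------------------------------
# template construction


def _sample_consensus(alignment: Sequence[str], rng: np.random.Generator) -> str:
    """Sample one residue per column from the column's observed frequencies."""
    cols = len(alignment[0])
    out = []
    for j in range(cols):
        residues = [s[j] for s in alignment if s[j] != "-"]
        out.append(residues[rng.integers(len(residues))])
    return "".join(out)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS_FOR_AA[aa][rng.integers(len(_CODONS_FOR_AA[aa]))]
                   for aa in protein)


def _random_codons(n: int, rng: np.random.Generator) -> str:
    return "".join(_NON_STOP_CODONS[i]
                   for i in rng.integers(len(_NON_STOP_CODONS), size=n))


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return "".join("ACGT"[i] for i in idx)


def build_element_template(
    superfamily: str,
    chromoviral: bool,
    ltr_len: int,
    domain_seed_alignments: dict[str, list[str]] | None = None,
    rng_seed: int = 0,
    *,
    template_id: str | None = None,
    tsd_len: int = 5,
    internal_len: int = 4500,
    tg_ca: bool = True,
) -> ElementTemplate:
    """Build a stop-free element template whose domains are back-translated
    sampled consensi of the packaged seed families.

    The pol-domain order follows the canonical superfamily layouts: Copia is
    GAG-AP-INT-RT-RH; Gypsy is GAG-AP-RT-RH-INT, with CHROMO appended after
    the integrase for chromoviruses. LTR termini default to the canonical
    5'-TG...CA-3' dinucleotides (``tg_ca=False`` disables this).
    """
    if chromoviral and superfamily != "Gypsy":
        raise ValueError("chromoviral templates must be Ty3/Gypsy")
    if not 100 <= ltr_len <= 600:
        raise ValueError("ltr_len must be in [100, 600]")
    if domain_seed_alignments is None:
        # domains descend from the template's superfamily branch, so shared
        # profiles (Gag/INT/RH) still separate the superfamilies
        domain_seed_alignments = seedbank.branch_seed_alignments(superfamily)
    rng = np.random.default_rng(rng_seed)

    layout = list(COPIA_LAYOUT if superfamily == "Copia" else GYPSY_LAYOUT)
    if chromoviral:
        layout.append("CHROMO")

    ltr = _random_dna(ltr_len, 0.45, rng)
    if tg_ca:
        ltr = "TG" + ltr[2:-2] + "CA"

    lead = _random_codons(30, rng)
    pieces = [lead]
    pos = len(lead)
    domain_coords: list[tuple[str, int, int]] = []
    for i, domain in enumerate(layout):
        profile = PROFILE_FOR[superfamily][domain]
        consensus = _sample_consensus(domain_seed_alignments[profile], rng)
        dna = _back_translate(consensus, rng)
        domain_coords.append((domain, pos, pos + len(dna)))
        pieces.append(dna)
        pos += len(dna)
        if i < len(layout) - 1:
            linker = _random_codons(15, rng)
            pieces.append(linker)
            pos += len(linker)
    pad = max(0, (internal_len - pos) // 3)
    pieces.append(_random_codons(pad, rng))
    internal = "".join(pieces)

    return ElementTemplate(
        template_id=template_id or f"{superfamily}{'_chromo' if chromoviral else ''}_{rng_seed}",
        superfamily=superfamily,
        chromoviral=chromoviral,
        ltr_seq=ltr,
        internal_seq=internal,
        domain_layout=tuple(domain_coords),
        tsd_len=tsd_len,
    )


def default_templates(rng_seed: int = 0, ltr_len: int = 300) -> list[ElementTemplate]:
    """One Ty1/Copia and one chromoviral Ty3/Gypsy template — the default
    two-lineage community used throughout the benchmark."""
    return [
        build_element_template("Copia", False, ltr_len, rng_seed=rng_seed * 2 + 1,
                               template_id=f"Copia_T{rng_seed}"),
        build_element_template("Gypsy", True, ltr_len, rng_seed=rng_seed * 2 + 2,
                               template_id=f"Gypsy_T{rng_seed}"),
    ]


def render_element(template: ElementTemplate) -> str:
    """Full element sequence: LTR + internal + identical LTR."""
    return template.ltr_seq + template.internal_seq + template.ltr_seq


# ---------------------------------------------------------------------------
# degradation


def _stop_substitution(codon: str, rng: np.random.Generator) -> tuple[int, str] | None:
    """A (position, base) single change turning ``codon`` into a stop, if any."""
    options = []
    for stop in STOP_CODONS:
        diffs = [k for k in range(3) if codon[k] != stop[k]]
        if len(diffs) == 1:
            options.append((diffs[0], stop[diffs[0]]))
    if not options:
        return None
    return options[rng.integers(len(options))]


def _apply_substitutions(
    seq: list[str],
    site_rate: np.ndarray,
    stop_bias: float,
    rng: np.random.Generator,
) -> int:
    hits = np.flatnonzero(rng.random(len(seq)) < site_rate)
    n = 0
    for i in hits:
        placed = False
        if stop_bias > 0 and rng.random() < stop_bias:
            c0 = 3 * (i // 3)
            codon = "".join(seq[c0:c0 + 3])
            if len(codon) == 3 and codon not in STOP_CODONS:
                sub = _stop_substitution(codon, rng)
                if sub is not None:
                    seq[c0 + sub[0]] = sub[1]
                    placed = True
        if not placed:
            alternatives = [b for b in "ACGT" if b != seq[i]]
            seq[i] = alternatives[rng.integers(3)]
        n += 1
    return n


def _apply_indels(seq: list[str], indel_rate: float, rng: np.random.Generator) -> int:
    if indel_rate <= 0:
        return 0
    hits = np.flatnonzero(rng.random(len(seq)) < indel_rate)
    n = 0
    for i in reversed(hits):  # right-to-left keeps earlier coordinates valid
        size = int(rng.integers(1, 4))
        if rng.random() < 0.5:
            del seq[i:i + size]
        else:
            ins = [("ACGT"[k]) for k in rng.integers(4, size=size)]
            seq[i:i] = ins
        n += 1
    return n


def degrade_sequence(dna: str, params: DegradationParams, rng_seed: int) -> str:
    """Mutate ``dna``: Binomial(len, point_rate) substitutions (stop-biased in
    frame +1 when ``stop_bias`` > 0) followed by indels. Deterministic given
    the seed."""
    if not dna:
        raise ValueError("empty sequence")
    rng = np.random.default_rng(rng_seed)
    seq = list(dna)
    _apply_substitutions(seq, np.full(len(seq), params.point_rate),
                         params.stop_bias, rng)
    _apply_indels(seq, params.indel_rate, rng)
    return "".join(seq)


def degrade_element(
    template: ElementTemplate,
    params: DegradationParams,
    rng: np.random.Generator,
    rate_scale: float = 1.0,
) -> tuple[str, int]:
    """Degrade a rendered copy of ``template`` with per-domain rate
    multipliers applied inside the internal ORF. Returns (sequence,
    substitution count). ``rate_scale`` scales the whole-copy rate — a crude
    insertion-age knob."""
    seq = list(render_element(template))
    site_rate = np.full(len(seq), params.point_rate * rate_scale)
    for domain, s, e in template.layout_in_element_coords():
        mult = params.domain_rate_multipliers.get(domain, 1.0)
        site_rate[s:e] = np.minimum(params.point_rate * rate_scale * mult, 1.0)
    n_sub = _apply_substitutions(seq, site_rate, params.stop_bias, rng)
    _apply_indels(seq, params.indel_rate, rng)
    return "".join(seq), n_sub


# ---------------------------------------------------------------------------
# implantation


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def expected_genome_gain(records: list[GroundTruthRecord],
                         templates: dict[str, ElementTemplate]) -> int:
    """Genome-length gain implied by ground truth: each record's span plus
    one extra TSD copy for every non-truncated insertion."""
    gain = 0
    for r in records:
        gain += r.length
        if r.state != "truncated":
            gain += templates[r.template_id].tsd_len
    return gain


def implant_elements(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GroundTruthRecord]]:
    """Simulate one genome: i.i.d. background plus implanted element copies.

    Non-truncated insertions are flanked by a target-site duplication of the
    template's ``tsd_len``; nested insertions land inside a previously
    implanted copy (depth capped at 2). Identical (config, seed) gives
    byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    templates = list(config.templates) or default_templates(config.seed)
    tdict = {t.template_id: t for t in templates}
    deg = config.degradation

    total_element_nt = sum(t.length for t in templates) * config.copies_per_template
    if config.background_len < total_element_nt:
        raise ValueError(
            f"background ({config.background_len} nt) too short to host "
            f"{total_element_nt} nt of requested element copies")

    genome = _random_dna(config.background_len, config.gc_content, rng)
    records: list[GroundTruthRecord] = []
    nest_depth: dict[int, int] = {}  # record index -> depth

    copies = [(t, k) for t in templates for k in range(config.copies_per_template)]
    for copy_i, (template, _k) in enumerate(copies):
        state = "intact"
        u = rng.random(3)
        if u[0] < deg.solo_ltr_prob:
            state = "solo_ltr"
        elif u[1] < deg.truncate_prob:
            state = "truncated"
        elif u[2] < deg.nest_prob and any(
                nest_depth.get(i, 0) < 2 and records[i].state not in ("solo_ltr",)
                for i in range(len(records))):
            state = "nested"

        if state == "solo_ltr":
            seq = list(template.ltr_seq)
            n_sub = _apply_substitutions(
                seq, np.full(len(seq), deg.point_rate), 0.0, rng)
            _apply_indels(seq, deg.indel_rate, rng)
            seq = "".join(seq)
        else:
            seq, n_sub = degrade_element(template, deg, rng)
            if state == "truncated":
                keep = 0.3 + 0.4 * rng.random()
                cut = int(len(seq) * keep)
                seq = seq[:cut] if rng.random() < 0.5 else seq[-cut:]
        if state == "intact" and n_sub > 0:
            state = "degraded"

        strand = "+"
        if config.random_strand and rng.random() < 0.5:
            strand = "-"
            seq = _revcomp(seq)

        # choose an insertion point
        if state == "nested":
            hosts = [i for i in range(len(records))
                     if nest_depth.get(i, 0) < 2 and records[i].state != "solo_ltr"]
            host = int(hosts[rng.integers(len(hosts))])
            hr = records[host]
            p = int(rng.integers(hr.start + 1, hr.end - 1))
            depth = nest_depth.get(host, 0) + 1
        else:
            # keep insertions out of existing element spans
            for _attempt in range(200):
                p = int(rng.integers(0, len(genome) + 1))
                if not any(r.start < p < r.end for r in records):
                    break
            depth = 0

        with_tsd = state != "truncated"
        tsd = template.tsd_len if with_tsd else 0
        if with_tsd:
            genome = genome[:p + tsd] + seq + genome[p:]
        else:
            genome = genome[:p] + seq + genome[p:]
        elem_start = p + tsd
        gain = len(seq) + tsd

        for i, r in enumerate(records):
            if r.start >= p:
                r.start += gain
                r.end += gain
            elif r.end > p:  # host of a nested insertion
                r.end += gain
        rec = GroundTruthRecord(
            contig=config.contig_name,
            start=elem_start,
            end=elem_start + len(seq),
            template_id=template.template_id,
            state=state,
            strand=strand,
            n_point_mutations=n_sub,
        )
        records.append(rec)
        nest_depth[len(records) - 1] = depth

    records.sort(key=lambda r: (r.contig, r.start, r.end))
    return {config.contig_name: genome}, records


def write_ground_truth(records: list[GroundTruthRecord],
                       gff3_path: str | Path,
                       tsv_path: str | Path | None = None) -> None:
    feats = [{
        "contig": r.contig, "start": r.start, "end": r.end,
        "strand": r.strand, "type": "LTR_retrotransposon",
        "attributes": {"template_id": r.template_id, "state": r.state,
                       "n_point_mutations": r.n_point_mutations},
    } for r in records]
    write_gff3(feats, gff3_path, source="ltrcensus_sim")
    if tsv_path is not None:
        import pandas as pd
        pd.DataFrame([r.__dict__ for r in records]).to_csv(
            tsv_path, sep="\t", index=False)


def write_genome(genome: dict[str, str], path: str | Path) -> None:
    write_fasta(genome, path)
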