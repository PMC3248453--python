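"""Six-frame translation, PSSM domain scanning and superfamily classification.

Each candidate element is translated in all six frames and scanned with
position-specific scoring matrices (gapless log-odds profiles) for the
eight retrotransposon protein domains: Gag, the two aspartic-protease
variants (RVP, Copia-associated; RVP_2, Gypsy-associated), the integrase
core (rve), the two reverse-transcriptase variants (RVT_1, Gypsy; RVT_2,
Copia), the two RT-flanking domains (RVT_thumb, RVT_connect — corroborating
evidence only, they never vote for a superfamily), an LTR-retrotransposon-
oriented RNase H, and the chromodomain that marks chromoviruses.

Classification follows the canonical rules: the RT/AP profile variants vote
for a superfamily; ties are broken by pol domain order (integrase last in
Gypsy, between protease and RT in Copia); an element is functional when it
retains at least one of Gag/INT/RT/AP/RH; chromoviral means a chromodomain
hit on a Gypsy element. An element carrying both Copia- and Gypsy-voting
hits is flagged as a complex locus (multiple insertions at one site).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq

from . import seedbank
from .seedbank import AMINO_ACIDS, BACKGROUND, DOMAIN_SPECS, VOTING_DOMAINS

__all__ = [
    "FrameTranslation",
    "ProteinProfile",
    "DomainHit",
    "ElementClassification",
    "six_frame_translate",
    "build_profile_from_alignment",
    "default_profiles",
    "scan_profiles",
    "scan_element",
    "classify_element",
]

FUNCTIONAL_DOMAINS = {"GAG", "AP_RVP", "AP_RVP2", "INT_rve",
                      "RT_RVT1", "RT_RVT2", "RH_LTR"}

STOP_SCORE = -8.0  # per '*' inside a scored window
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_STOP_COL, _UNKNOWN_COL = 20, 21


@dataclass(frozen=True)
class FrameTranslation:
    frame: int  # +1..+3, -1..-3
    protein: str
    offset: int  # nt offset of the frame on its strand
    nt_len: int  # length of the translated nucleotide sequence

    def aa_to_nt(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Map a frame-local aa interval back to element nt coordinates."""
        s = self.offset + 3 * aa_start
        e = self.offset + 3 * aa_end
        if self.frame > 0:
            return s, e
        return self.nt_len - e, self.nt_len - s


def six_frame_translate(dna: str) -> list[FrameTranslation]:
    """Translate in six frames; stops are '*', ambiguous codons 'X'."""
    dna = dna.upper()
    out: list[FrameTranslation] = []
    fwd = Seq(dna)
    rev = fwd.reverse_complement()
    for strand, seq in ((1, fwd), (-1, rev)):
        for off in range(3):
            sub = seq[off:len(seq) - (len(seq) - off) % 3]
            prot = str(sub.translate()) if len(sub) >= 3 else ""
            out.append(FrameTranslation(frame=strand * (off + 1),
                                        protein=prot, offset=off,
                                        nt_len=len(dna)))
    return out


@dataclass
class ProteinProfile:
    name: str
    matrix: np.ndarray  # (columns, 22): 20 residues + '*' + unknown
    length: int
    score_threshold: float
    superfamily_association: str  # Copia | Gypsy | neutral

    @property
    def max_score(self) -> float:
        return float(self.matrix[:, :20].max(axis=1).sum())

    def to_json_dict(self) -> dict:
        return {"name": self.name, "length": self.length,
                "score_threshold": self.score_threshold,
                "superfamily_association": self.superfamily_association,
                "matrix": self.matrix[:, :20].round(4).tolist()}


def _encode_protein(protein: str) -> np.ndarray:
    out = np.full(len(protein), _UNKNOWN_COL, dtype=np.int64)
    for i, aa in enumerate(protein):
        if aa == "*":
            out[i] = _STOP_COL
        else:
            out[i] = _AA_INDEX.get(aa, _UNKNOWN_COL)
    return out


def build_profile_from_alignment(
    alignment: list[str],
    pseudocount: float = 0.5,
    background: np.ndarray = BACKGROUND,
    *,
    name: str = "profile",
    association: str = "neutral",
    n_null: int = 2000,
    rng_seed: int = 7,
) -> ProteinProfile:
    """Per-column log-odds (bits) with additive pseudocounts.

    Columns with >=50% gaps are discarded. The score threshold comes from an
    empirical null: windows of background-sampled residues are scored and
    the threshold is set well above their range (mean + 8 SD), with a floor
    of 30% of the profile's maximum attainable score so that even a short,
    well-conserved profile stays specific on genome-scale scans.
    """
    if len(alignment) < 5:
        raise ValueError("need at least 5 seed sequences to build a profile")
    ncols_in = len(alignment[0])
    if any(len(s) != ncols_in for s in alignment):
        raise ValueError("seed alignment rows differ in length")

    kept_cols = [j for j in range(ncols_in)
                 if sum(s[j] == "-" for s in alignment) < 0.5 * len(alignment)]
    n = len(alignment)
    mat = np.zeros((len(kept_cols), 22))
    for row, j in enumerate(kept_cols):
        counts = np.zeros(20)
        observed = 0
        for s in alignment:
            aa = s[j]
            if aa in _AA_INDEX:
                counts[_AA_INDEX[aa]] += 1
                observed += 1
        freqs = (counts + pseudocount * background) / (observed + pseudocount)
        mat[row, :20] = np.log2(freqs / background)
    mat[:, _STOP_COL] = STOP_SCORE
    mat[:, _UNKNOWN_COL] = 0.0

    rng = np.random.default_rng(rng_seed)
    L = len(kept_cols)
    null_idx = rng.choice(20, size=(n_null, L), p=background)
    null_scores = mat[np.arange(L), null_idx].sum(axis=1)
    mu, sd = float(null_scores.mean()), float(null_scores.std())
    smax = float(mat[:, :20].max(axis=1).sum())
    threshold = max(mu + 8.0 * sd, 0.3 * smax)

    return ProteinProfile(name=name, matrix=mat, length=L,
                          score_threshold=threshold,
                          superfamily_association=association)


@lru_cache(maxsize=None)
def default_profiles() -> dict[str, ProteinProfile]:
    """Profiles for all packaged domain families."""
    bank = seedbank.seed_alignments()
    return {name: build_profile_from_alignment(
                bank[name], name=name,
                association=DOMAIN_SPECS[name][1])
            for name in DOMAIN_SPECS}


@dataclass
class DomainHit:
    element_id: str
    domain: str
    frame: int
    aa_start: int
    aa_end: int
    nt_start: int
    nt_end: int
    score: float


def _window_scores(enc: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    L = matrix.shape[0]
    W = len(enc) - L + 1
    if W <= 0:
        return np.empty(0)
    scores = np.zeros(W)
    for i in range(L):
        scores += matrix[i, enc[i:i + W]]
    return scores


def scan_profiles(frames: list[FrameTranslation],
                  profiles: dict[str, ProteinProfile],
                  element_id: str = "") -> list[DomainHit]:
    """Score every window of every frame against every profile; report
    windows at or above threshold after per-frame, per-profile greedy
    non-overlap resolution (best score first)."""
    hits: list[DomainHit] = []
    for fr in frames:
        if not fr.protein:
            continue
        enc = _encode_protein(fr.protein)
        for profile in profiles.values():
            scores = _window_scores(enc, profile.matrix)
            above = np.flatnonzero(scores >= profile.score_threshold)
            if len(above) == 0:
                continue
            order = above[np.argsort(-scores[above], kind="stable")]
            occupied: list[tuple[int, int]] = []
            for p in order:
                a, b = int(p), int(p) + profile.length
                if any(a < e and s < b for s, e in occupied):
                    continue
                occupied.append((a, b))
                nt_s, nt_e = fr.aa_to_nt(a, b)
                hits.append(DomainHit(
                    element_id=element_id, domain=profile.name,
                    frame=fr.frame, aa_start=a, aa_end=b,
                    nt_start=nt_s, nt_end=nt_e,
                    score=float(scores[p])))
    hits.sort(key=lambda h: (h.nt_start, h.nt_end, h.domain))
    return hits


def scan_element(dna: str, profiles: dict[str, ProteinProfile] | None = None,
                 element_id: str = "") -> list[DomainHit]:
    if profiles is None:
        profiles = default_profiles()
    return scan_profiles(six_frame_translate(dna), profiles, element_id)


@dataclass
class ElementClassification:
    superfamily: str  # Copia | Gypsy | unclassified
    chromoviral: bool
    functional: bool
    order_consistent: bool
    complex_locus: bool
    evidence: list[tuple[str, list[DomainHit]]] = field(default_factory=list)


_CANONICAL_POL_ORDER = {
    "Copia": ["GAG", "AP_RVP", "INT_rve", "RT_RVT2", "RH_LTR"],
    "Gypsy": ["GAG", "AP_RVP2", "RT_RVT1", "RH_LTR", "INT_rve"],
}


def _order_vote(hits: list[DomainHit]) -> str:
    """Tie-break by pol domain order: INT after RH => Gypsy; INT before RT
    => Copia."""
    by_domain: dict[str, DomainHit] = {}
    for h in sorted(hits, key=lambda h: -h.score):
        base = h.domain.split("_")[0]
        by_domain.setdefault(base, h)
    int_h = by_domain.get("INT")
    rh_h = by_domain.get("RH")
    rt_h = by_domain.get("RT")
    strand = -1 if sum(h.frame < 0 for h in hits) > len(hits) / 2 else 1

    def pos(h: DomainHit) -> float:
        return strand * (h.nt_start + h.nt_end) / 2

    if int_h and rh_h and pos(int_h) > pos(rh_h):
        return "Gypsy"
    if int_h and rt_h and pos(int_h) < pos(rt_h):
        return "Copia"
    return "unclassified"


def classify_element(hits: list[DomainHit]) -> ElementClassification:
    """Classify one element from its domain hits (see module docstring)."""
    evidence: list[tuple[str, list[DomainHit]]] = []
    votes = {"Copia": [], "Gypsy": []}
    for h in hits:
        if h.domain in VOTING_DOMAINS:
            assoc = seedbank.domain_association(h.domain)
            votes[assoc].append(h)

    complex_locus = bool(votes["Copia"]) and bool(votes["Gypsy"])
    if complex_locus:
        evidence.append(("both-superfamily RT/AP hits (complex locus)",
                         votes["Copia"] + votes["Gypsy"]))

    n_c, n_g = len(votes["Copia"]), len(votes["Gypsy"])
    if n_c == n_g == 0:
        superfamily = _order_vote(hits)
        if superfamily != "unclassified":
            evidence.append(("pol domain order", hits))
    elif n_c > n_g:
        superfamily = "Copia"
        evidence.append(("RT/AP profile majority", votes["Copia"]))
    elif n_g > n_c:
        superfamily = "Gypsy"
        evidence.append(("RT/AP profile majority", votes["Gypsy"]))
    else:
        superfamily = _order_vote(hits)
        evidence.append(("profile vote tie broken by domain order", hits))

    chromo_hits = [h for h in hits if h.domain == "CHROMO"]
    chromoviral = bool(chromo_hits) and superfamily == "Gypsy"
    if chromoviral:
        evidence.append(("chromodomain on a Gypsy element", chromo_hits))

    functional = any(h.domain in FUNCTIONAL_DOMAINS for h in hits)

    order_consistent = True
    if superfamily in _CANONICAL_POL_ORDER and hits:
        strand = -1 if sum(h.frame < 0 for h in hits) > len(hits) / 2 else 1
        best: dict[str, DomainHit] = {}
        for h in sorted(hits, key=lambda h: -h.score):
            best.setdefault(h.domain, h)
        observed = sorted(
            (d for d in best if d in _CANONICAL_POL_ORDER[superfamily]),
            key=lambda d: strand * (best[d].nt_start + best[d].nt_end))
        canonical = [d for d in _CANONICAL_POL_ORDER[superfamily] if d in observed]
        order_consistent = observed == canonical

    return ElementClassification(
        superfamily=superfamily, chromoviral=chromoviral,
        functional=functional, order_consistent=order_consistent,
        complex_locus=complex_locus, evidence=evidence)
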