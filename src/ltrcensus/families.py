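"""Family clustering at 80% nucleotide identity and most-successful-element
selection.

Families follow the cd-hit-est convention: elements are processed longest
first; each joins the first existing family whose representative (the
founding, longest member) it matches at >= the identity threshold, with
identity defined as matching columns of a global alignment divided by the
length of the shorter sequence. Both orientations are tried during
clustering, since elements may have been detected on either strand.

The most successful element of a genome is the longest member of the
largest family (ties: larger total nt, then lexicographic family id) whose
pol-region domains all lie in a single reading frame and which is not a
complex locus; singleton-only genomes yield none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Seq import Seq

__all__ = [
    "Family",
    "MostSuccessfulElement",
    "global_identity",
    "greedy_cluster",
    "select_most_successful",
]

_POL_BASES = {"AP", "RT", "RH", "INT"}


def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _nt_aligner()


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def global_identity(a: str, b: str, *, both_strands: bool = False) -> float:
    """Matching columns of a global alignment (match +1, mismatch -1, gap
    open -5, gap extend -1) divided by the length of the shorter sequence.

    With ``both_strands`` the reverse complement of ``b`` is also tried and
    the larger identity returned.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    ident = counts.identities / min(len(a), len(b))
    if both_strands:
        ident = max(ident, global_identity(a, _revcomp(b)))
    return min(ident, 1.0)


def _kmer_set(s: str, k: int) -> set[str]:
    return {s[i:i + k] for i in range(len(s) - k + 1)}


@dataclass
class Family:
    family_id: str
    genome_id: str
    member_ids: list[str]
    representative_id: str
    size: int = 0

    def __post_init__(self) -> None:
        self.size = len(self.member_ids)


def greedy_cluster(
    elements: dict[str, str],
    threshold: float = 0.8,
    word_len: int = 10,
    *,
    genome_id: str = "genome",
    min_shared_kmer_fraction: float = 0.02,
) -> list[Family]:
    """Greedy incremental clustering of one genome's elements.

    ``elements`` maps element id to nucleotide sequence. A shared-k-mer
    prefilter (fraction of the shorter sequence's k-mers found in the
    representative, either strand) skips hopeless alignments.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0,1]")
    order = sorted(elements, key=lambda eid: (-len(elements[eid]), eid))
    reps: list[str] = []  # representative element ids, in family order
    rep_kmers: list[tuple[set[str], set[str]]] = []
    members: list[list[str]] = []

    for eid in order:
        seq = elements[eid]
        kmers = _kmer_set(seq, word_len)
        placed = False
        for fi, rep in enumerate(reps):
            fwd, rev = rep_kmers[fi]
            denom = max(1, min(len(kmers), len(fwd)))
            share = max(len(kmers & fwd), len(kmers & rev)) / denom
            if share < min_shared_kmer_fraction:
                continue
            if global_identity(elements[rep], seq, both_strands=True) >= threshold:
                members[fi].append(eid)
                placed = True
                break
        if not placed:
            reps.append(eid)
            rep_kmers.append((kmers, _kmer_set(_revcomp(seq), word_len)))
            members.append([eid])

    return [Family(family_id=f"{genome_id}_fam{fi + 1:03d}",
                   genome_id=genome_id,
                   member_ids=members[fi],
                   representative_id=reps[fi])
            for fi in range(len(reps))]


@dataclass
class MostSuccessfulElement:
    genome_id: str
    element_id: str
    family_id: str
    family_size: int
    selection_path: list[tuple[str, str]] = field(default_factory=list)


def select_most_successful(
    families: list[Family],
    annotations: dict[str, dict],
    element_lengths: dict[str, int],
) -> MostSuccessfulElement | None:
    """Pick the genome's most successful element, or None.

    ``annotations[element_id]`` carries ``classification`` (an
    ElementClassification) and ``hits`` (DomainHits). The largest family
    with >=2 members is chosen (ties: larger total nt, then lexicographic
    family id); its members are walked longest-first and the first member
    whose pol-region domain hits all lie in one frame and which is not a
    complex locus wins. Rejections are recorded on the selection path.
    """
    candidates = [f for f in families if f.size >= 2]
    if not candidates:
        return None

    def fam_key(f: Family) -> tuple:
        total_nt = sum(element_lengths[m] for m in f.member_ids)
        return (-f.size, -total_nt, f.family_id)

    family = min(candidates, key=fam_key)
    path: list[tuple[str, str]] = []
    for eid in sorted(family.member_ids,
                      key=lambda m: (-element_lengths[m], m)):
        ann = annotations.get(eid, {})
        cls = ann.get("classification")
        hits = ann.get("hits", [])
        pol_hits = [h for h in hits if h.domain.split("_")[0] in _POL_BASES]
        if not pol_hits:
            path.append((eid, "no detectable pol-region domains"))
            continue
        frames = {h.frame for h in pol_hits}
        if len(frames) > 1:
            path.append((eid, f"pol domains split across frames {sorted(frames)}"))
            continue
        if cls is not None and cls.complex_locus:
            path.append((eid, "complex locus (both superfamilies' hits)"))
            continue
        return MostSuccessfulElement(
            genome_id=family.genome_id, element_id=eid,
            family_id=family.family_id, family_size=family.size,
            selection_path=path)
    return None
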