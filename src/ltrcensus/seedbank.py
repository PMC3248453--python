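"""Synthetic seed families for the retrotransposon protein domains.

Real annotation pipelines build their domain profiles from curated seed
alignments (Pfam-style). This package instead ships a deterministic,
self-contained bank of synthetic seed families: one conserved ancestral
protein per domain, plus a set of diverged copies that together form a
gap-free seed alignment. Element templates in :mod:`ltrcensus.simulate`
back-translate consensi sampled from these same families, so the profiles
built from the bank can rediscover the domains they describe — the
round-trip that the whole synthetic benchmark rests on.

Everything here is synthetic stand-in data; the families carry the names
and superfamily associations of the real Pfam domains (RVT_1 vs RVT_2 for
the Gypsy vs Copia reverse transcriptases, RVP vs RVP_2 for the two
aspartic proteases, rve for the integrase core, a dedicated LTR-oriented
RNase H, Gag, chromodomain, and the two RT-flanking domains RVT_thumb and
RVT_connect) but none of their sequence content.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Robinson-Robinson style background frequencies, renormalised over the 20
# canonical residues in AMINO_ACIDS order.
BACKGROUND = np.array([
    0.0787, 0.0133, 0.0535, 0.0662, 0.0397, 0.0695, 0.0229, 0.0590,
    0.0595, 0.0966, 0.0238, 0.0441, 0.0483, 0.0399, 0.0539, 0.0683,
    0.0541, 0.0667, 0.0109, 0.0304,
])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

#: domain name -> (alignment length in aa, superfamily association)
DOMAIN_SPECS: dict[str, tuple[int, str]] = {
    "GAG": (130, "neutral"),
    "AP_RVP": (100, "Copia"),
    "AP_RVP2": (100, "Gypsy"),
    "INT_rve": (150, "neutral"),
    "RT_RVT1": (180, "Gypsy"),
    "RT_RVT2": (180, "Copia"),
    "RVT_thumb": (70, "neutral"),
    "RVT_connect": (80, "neutral"),
    "RH_LTR": (130, "neutral"),
    "CHROMO": (55, "Gypsy"),
}

#: profiles whose hits vote for a superfamily during classification
VOTING_DOMAINS = {"RT_RVT1", "RT_RVT2", "AP_RVP", "AP_RVP2"}

N_SEED_SEQUENCES = 8
SEED_DIVERGENCE = 0.08  # substitutions per site between branch and each seed
BRANCH_DIVERGENCE = 0.15  # each superfamily branch vs the family ancestor

_BANK_SEED = 20111229  # fixed: the bank is package data, not a tunable


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=BACKGROUND)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    hit = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hit):
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _family(rng: np.random.Generator, length: int) -> dict[str, object]:
    """One domain family with an ancient Copia/Gypsy split.

    The superfamilies diverged deeply, so even the domains scored by a
    single shared profile (Gag, integrase core, RNase H) form separate
    superfamily clans. Each family therefore carries two branches, one per
    superfamily, each represented by half the seed sequences; profiles are
    built from all seeds and detect both branches.
    """
    ancestor = _random_protein(rng, length)
    branches = {sf: _mutate_protein(rng, ancestor, BRANCH_DIVERGENCE)
                for sf in ("Copia", "Gypsy")}
    branch_seeds = {sf: [_mutate_protein(rng, anc, SEED_DIVERGENCE)
                         for _ in range(N_SEED_SEQUENCES // 2)]
                    for sf, anc in branches.items()}
    return {"ancestor": ancestor, "branches": branches,
            "branch_seeds": branch_seeds,
            "seeds": branch_seeds["Copia"] + branch_seeds["Gypsy"]}


@lru_cache(maxsize=None)
def _bank() -> dict[str, dict[str, object]]:
    rng = np.random.default_rng(_BANK_SEED)
    return {name: _family(rng, length)
            for name, (length, _assoc) in DOMAIN_SPECS.items()}


def seed_alignments() -> dict[str, list[str]]:
    """Gap-free seed alignment (list of equal-length sequences) per domain."""
    return {name: list(fam["seeds"]) for name, fam in _bank().items()}


def branch_seed_alignments(superfamily: str) -> dict[str, list[str]]:
    """Per-domain seed sequences of one superfamily's branch."""
    return {name: list(fam["branch_seeds"][superfamily])  # type: ignore[index]
            for name, fam in _bank().items()}


def domain_ancestor(name: str, superfamily: str | None = None) -> str:
    """The ancestral (consensus-like) protein of one domain family, or of
    one superfamily's branch of it."""
    fam = _bank()[name]
    if superfamily is None:
        return fam["ancestor"]  # type: ignore[return-value]
    return fam["branches"][superfamily]  # type: ignore[index]


def domain_association(name: str) -> str:
    return DOMAIN_SPECS[name][1]


@lru_cache(maxsize=None)
def outgroup_domains(n_taxa: int = 2) -> dict[str, dict[str, str]]:
    """Synthetic Bel/Pao-like outgroup: {taxon: {domain: protein}}.

    Stand-ins for the Drosophila Bel/Pao reference elements used to root
    the most-successful-element phylogeny. Each outgroup domain descends
    from an independent ancestor, so the outgroup sits far from both the
    Copia-like and Gypsy-like ingroup sequences.
    """
    rng = np.random.default_rng(_BANK_SEED + 1)
    core = {"RT": 180, "INT": 150, "RH": 130, "AP": 100}
    ancestors = {d: _random_protein(rng, ln) for d, ln in core.items()}
    taxa = {}
    for i in range(n_taxa):
        label = f"BelPao_outgroup_{i + 1}"
        taxa[label] = {d: _mutate_protein(rng, a, 0.08)
                       for d, a in ancestors.items()}
    return taxa
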