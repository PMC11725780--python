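"""Synthetic pedigree, genotype, radiocarbon and isotope data with known truth.

The generator emulates the data regime of a small elite burial group
analysed with low-coverage ancient DNA: a four-generation pedigree with six
sampled and several unsampled individuals, pseudohaploid observation of a
SNP capture panel at 0.01-1.2x coverage, mitochondrial lineage labels,
sex-chromosome read counts, radiocarbon determinations drawn under
diet-weighted terrestrial/marine curve mixing, and stable-isotope values
from linear diet mixing.  Every stage records ground truth (haplotype
founder origins, true kinship, true event years) so downstream estimators
can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genotype_io import MISSING, GenotypePanel, SNPPanel
from .pedigree import Individual, InvalidPedigreeError, Pedigree
from .chronology import C14Determination, CalCurve, ce_to_bp

__all__ = [
    "AlleleFrequencySet",
    "ObservationModel",
    "DiploidGenotypes",
    "ReadCounts",
    "draw_frequencies",
    "gene_drop",
    "degrade_to_reads",
    "pseudohaploid_call",
    "simulate_sexchr_counts",
    "simulate_c14",
    "simulate_context_dates",
    "simulate_isotopes",
    "cao_family_pedigree",
    "second_cousin_pedigree",
    "DEPTH_PRESETS",
    "STUDY_MARINE_FRACS",
]

TOTAL_MAP_CM = 3545.0  # default autosomal genetic map length
N_CHROM = 22


def default_chromosome_lengths(total_cm: float = TOTAL_MAP_CM) -> np.ndarray:
    """Decreasing chromosome lengths summing to ``total_cm``."""
    w = np.arange(N_CHROM, 0, -1, dtype=float) + 4.0
    return total_cm * w / w.sum()


@dataclass
class AlleleFrequencySet:
    freq: np.ndarray  # population frequency of the alternate allele
    chrom: np.ndarray  # 1..22
    cm: np.ndarray  # genetic position within chromosome
    chrom_lengths: np.ndarray

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        if np.any((self.freq <= 0) | (self.freq >= 1)):
            raise ValueError("frequencies must lie strictly in (0, 1)")
        for c in np.unique(self.chrom):
            pos = self.cm[self.chrom == c]
            if np.any(np.diff(pos) < 0):
                raise ValueError("map positions must be nondecreasing")

    def __len__(self):
        return len(self.freq)

    def snp_panel(self, rng: Optional[np.random.Generator] = None) -> SNPPanel:
        rng = rng or np.random.default_rng(0)
        n = len(self)
        refalt = rng.choice(len(_PAIRS), size=n)
        ref = np.array([_PAIRS[i][0] for i in refalt], dtype=object)
        alt = np.array([_PAIRS[i][1] for i in refalt], dtype=object)
        return SNPPanel(
            ids=np.array([f"snp{i}" for i in range(n)], dtype=object),
            chrom=self.chrom.astype(str).astype(object),
            cm=self.cm,
            bp=np.maximum((self.cm * 1_000_000).astype(np.int64), 1),
            ref=ref,
            alt=alt,
        )


_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]


@dataclass
class ObservationModel:
    mean_depth: float = 1.0  # reads per site
    base_error: float = 0.001
    # effective residual post-trim deamination miscall rate (0 -> 1 flips)
    damage_rate: float = 0.005
    missing_rate: float = 0.0  # capture dropout on top of Poisson zeros

    def __post_init__(self):
        for name in ("base_error", "damage_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be nonnegative")


@dataclass
class DiploidGenotypes:
    ids: list[str]
    freqs: AlleleFrequencySet
    haplotypes: np.ndarray  # (n_ind, 2, n_snps) uint8 alleles
    origins: np.ndarray  # (n_ind, 2, n_snps) int32 founder-haplotype labels

    @property
    def genotypes(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1).astype(np.int8)

    def realized_kinship(self, a: str, b: str) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        oa, ob = self.origins[ia], self.origins[ib]
        m = sum(
            (oa[i] == ob[j]).mean() for i in range(2) for j in range(2)
        )
        return float(m) / 4.0

    def ibd_state_fractions(self, a: str, b: str) -> tuple[float, float, float]:
        ia, ib = self.ids.index(a), self.ids.index(b)
        oa, ob = self.origins[ia], self.origins[ib]
        n = oa.shape[1]
        share = np.zeros(n, dtype=int)
        m00 = oa[0] == ob[0]
        m01 = oa[0] == ob[1]
        m10 = oa[1] == ob[0]
        m11 = oa[1] == ob[1]
        ibd2 = (m00 & m11) | (m01 & m10)
        ibd1 = (m00 | m01 | m10 | m11) & ~ibd2
        share[ibd1] = 1
        share[ibd2] = 2
        return (
            float((share == 0).mean()),
            float((share == 1).mean()),
            float((share == 2).mean()),
        )


@dataclass
class ReadCounts:
    ids: list[str]
    depth: np.ndarray  # (n_ind, n_snps) int
    alt: np.ndarray  # (n_ind, n_snps) count of alternate-allele reads
    freqs: Optional[AlleleFrequencySet] = None


def draw_frequencies(
    n_snps: int,
    beta_shape: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
    total_cm: float = TOTAL_MAP_CM,
) -> AlleleFrequencySet:
    """Draw a SNP panel's allele frequencies and genetic map.

    Frequencies are Beta(a, b) draws truncated to [0.01, 0.99] (an
    ascertained capture panel has no near-fixed sites); map positions are
    uniform within chromosomes whose lengths sum to ``total_cm``.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    a, b = beta_shape
    if a <= 0 or b <= 0:
        raise ValueError("beta shape parameters must be positive")
    rng = np.random.default_rng(seed)
    freq = np.clip(rng.beta(a, b, size=n_snps), 0.01, 0.99)
    lengths = default_chromosome_lengths(total_cm)
    probs = lengths / lengths.sum()
    chrom = rng.choice(np.arange(1, N_CHROM + 1), size=n_snps, p=probs)
    cm = rng.uniform(0, 1, size=n_snps)
    order = np.lexsort((cm, chrom))
    chrom, cm, freq = chrom[order], cm[order], freq[order]
    cm = cm * lengths[chrom - 1]
    # sort within chromosome
    order = np.lexsort((cm, chrom))
    return AlleleFrequencySet(
        freq=freq[order], chrom=chrom[order], cm=cm[order],
        chrom_lengths=lengths,
    )


def _meiosis(
    haps: np.ndarray,
    origins: np.ndarray,
    freqs: AlleleFrequencySet,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: Poisson crossovers (no interference) on the cM map."""
    n = len(freqs)
    gam = np.empty(n, dtype=haps.dtype)
    gor = np.empty(n, dtype=origins.dtype)
    for ci, length in enumerate(freqs.chrom_lengths, start=1):
        m = freqs.chrom == ci
        if not m.any():
            continue
        pos = freqs.cm[m]
        n_x = rng.poisson(length / 100.0)
        breaks = np.sort(rng.uniform(0, length, size=n_x))
        start = rng.integers(2)
        seg = (np.searchsorted(breaks, pos) + start) % 2
        idx = np.where(m)[0]
        gam[idx] = np.where(seg == 0, haps[0, idx], haps[1, idx])
        gor[idx] = np.where(seg == 0, origins[0, idx], origins[1, idx])
    return gam, gor


def gene_drop(
    pedigree: Pedigree, freqs: AlleleFrequencySet, seed: int = 0
) -> DiploidGenotypes:
    """Drop genes through a pedigree.

    Founders receive Hardy-Weinberg haplotypes; each non-founder inherits
    one recombinant gamete per parent (Poisson crossovers, 1 per 100 cM).
    Founder-haplotype origin labels are carried along as IBD truth.
    """
    order = pedigree.topological_order()  # raises InvalidPedigreeError on cycles
    rng = np.random.default_rng(seed)
    n = len(freqs)
    ids = list(pedigree.ids)
    index = {iid: k for k, iid in enumerate(ids)}
    haps = np.zeros((len(ids), 2, n), dtype=np.uint8)
    origins = np.zeros((len(ids), 2, n), dtype=np.int32)
    label = 0
    for iid in order:
        k = index[iid]
        mo, fa = pedigree.parents(iid)
        for h, parent in enumerate((mo, fa)):
            if parent is None:
                haps[k, h] = rng.random(n) < freqs.freq
                origins[k, h] = label
                label += 1
            else:
                pk = index[parent]
                haps[k, h], origins[k, h] = _meiosis(
                    haps[pk], origins[pk], freqs, rng
                )
    return DiploidGenotypes(ids=ids, freqs=freqs, haplotypes=haps, origins=origins)


def degrade_to_reads(
    geno: DiploidGenotypes,
    model: ObservationModel,
    seed: int = 0,
    depths: Optional[dict[str, float]] = None,
    individuals: Optional[list[str]] = None,
) -> ReadCounts:
    """Observe diploid truth through the sequencing model.

    Per-site depth is Poisson(mean_depth) (per-individual override via
    ``depths``); each read samples one of the two haplotypes, flips with the
    base error, and additionally flips reference->alternate with the damage
    rate (deamination-like asymmetric miscalls).
    """
    rng = np.random.default_rng(seed)
    ids = individuals if individuals is not None else list(geno.ids)
    n = geno.haplotypes.shape[2]
    depth = np.empty((len(ids), n), dtype=np.int64)
    alt = np.empty((len(ids), n), dtype=np.int64)
    for r, iid in enumerate(ids):
        k = geno.ids.index(iid)
        d = depths.get(iid, model.mean_depth) if depths else model.mean_depth
        dp = rng.poisson(d, size=n)
        if model.missing_rate > 0:
            dp[rng.random(n) < model.missing_rate] = 0
        g = geno.haplotypes[k].sum(axis=0)
        p_alt = g / 2.0
        e = model.base_error
        p_eff = p_alt * (1 - e) + (1 - p_alt) * e
        p_eff = p_eff + (1 - p_eff) * model.damage_rate
        depth[r] = dp
        alt[r] = rng.binomial(dp, p_eff)
    return ReadCounts(ids=list(ids), depth=depth, alt=alt, freqs=geno.freqs)


def pseudohaploid_call(
    reads: ReadCounts,
    seed: int = 0,
    snp: Optional[SNPPanel] = None,
    sexes: Optional[list[str]] = None,
) -> GenotypePanel:
    """One random read per covered site; uncovered sites are missing."""
    rng = np.random.default_rng(seed)
    n_ind, n = reads.depth.shape
    geno = np.full((n_ind, n), MISSING, dtype=np.int8)
    for r in range(n_ind):
        cov = reads.depth[r] > 0
        p_alt = np.zeros(n)
        p_alt[cov] = reads.alt[r, cov] / reads.depth[r, cov]
        pick_alt = rng.random(n) < p_alt
        geno[r, cov] = np.where(pick_alt[cov], 2, 0)
    if snp is None:
        if reads.freqs is None:
            raise ValueError("need a SNPPanel or attached frequencies")
        snp = reads.freqs.snp_panel(np.random.default_rng(12345))
    return GenotypePanel(
        snp=snp, genotypes=geno, ids=list(reads.ids), sexes=sexes,
        pseudohaploid=True,
    )


# expected read-pool composition used by the sex-count simulator: the male
# Y share puts Ry well above 0.075, the female Y mismapping rate well below
# 0.016 at high counts.
SEXCHR_COMPOSITION = {
    "M": {"aut": 0.950, "X": 0.0455, "Y": 0.0045},
    "F": {"aut": 0.950, "X": 0.04975, "Y": 0.00025},
}


def simulate_sexchr_counts(
    sex: str, n_reads: int, mappable_fraction_y: float = 1.0, seed: int = 0
) -> dict[str, int]:
    """Multinomial read counts over autosomes / X / Y for one individual."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    comp = SEXCHR_COMPOSITION[sex]
    rng = np.random.default_rng(seed)
    p = np.array([comp["aut"], comp["X"], comp["Y"] * mappable_fraction_y])
    p = p / p.sum()
    n_aut, n_x, n_y = rng.multinomial(n_reads, p)
    return {"nAut": int(n_aut), "nX": int(n_x), "nY": int(n_y)}


def simulate_c14(
    pedigree: Pedigree,
    tissue_ages: dict[str, float],
    marine_fracs: dict[str, tuple[float, float]],
    delta_r: float,
    terr: CalCurve,
    marine: CalCurve,
    sigma_lab: float = 20.0,
    seed: int = 0,
) -> list[C14Determination]:
    """Simulate 14C determinations for sampled individuals.

    Each dated tissue formed at ``birth + tissue_age``; the measured age is
    Normal(mixed-curve mean at that year, sqrt(curve sigma^2 + lab sigma^2))
    with the marine component of the mixture offset by ``delta_r``.  The
    recorded determination carries the (noisy prior) marine fraction, not
    the truth.
    """
    from .chronology import mixed_curve

    rng = np.random.default_rng(seed)
    out = []
    for iid, tage in tissue_ages.items():
        ind = pedigree.members[iid]
        if ind.birth_year is None:
            raise ValueError(f"{iid} has no birth year")
        event_bp = ce_to_bp(ind.birth_year + tage)
        p, p_sd = marine_fracs.get(iid, (0.0, 0.0))
        mu, sd = mixed_curve(terr, marine, p, delta_r, event_bp)
        age = rng.normal(float(mu), math_hypot(float(sd), sigma_lab))
        out.append(
            C14Determination(
                lab_id=f"SIM-{iid}",
                age_bp=float(age),
                sigma=sigma_lab,
                individual=iid,
                material="human tissue",
                tissue_age_offset=tage,
                marine_frac=p,
                marine_frac_sd=p_sd,
            )
        )
    return out


def math_hypot(a: float, b: float) -> float:
    return float(np.hypot(a, b))


def simulate_context_dates(
    deposition_year_ce: float,
    n: int,
    terr: CalCurve,
    sigma_lab: float = 20.0,
    seed: int = 0,
    inbuilt_age_max: float = 15.0,
) -> list[C14Determination]:
    """Terrestrial context materials deposited with the burial event.

    Each material formed up to ``inbuilt_age_max`` years before deposition
    (short-lived plant matter, textiles, wood).
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        formed_ce = deposition_year_ce - rng.uniform(0, inbuilt_age_max)
        mu, sd = terr.at(ce_to_bp(formed_ce))
        age = rng.normal(float(mu), math_hypot(float(sd), sigma_lab))
        out.append(
            C14Determination(
                lab_id=f"CTX-{i + 1}",
                age_bp=float(age),
                sigma=sigma_lab,
                individual=None,
                material="terrestrial material",
            )
        )
    return out


# ---------------------------------------------------------------------
# isotopes
# ---------------------------------------------------------------------

def simulate_isotopes(
    diet_config: dict[str, dict[str, float]],
    endmembers=None,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Generate per-individual isotope records by linear diet mixing.

    ``diet_config`` maps individual id -> {'pC4': x, 'pMarine': y}.  Enamel
    carbon mixes C3/C4 plant endpoints plus the enamel-diet spacing;
    collagen nitrogen mixes the marine and terrestrial protein endpoints.
    """
    from .isotopes import Endmembers

    em = endmembers or Endmembers()
    rng = np.random.default_rng(seed)
    records = {}
    for iid, cfg in diet_config.items():
        p_c4 = cfg["pC4"]
        p_mar = cfg["pMarine"]
        for name, v in (("pC4", p_c4), ("pMarine", p_mar)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{iid}: {name} must be in [0, 1]")
        d13c_diet = (1 - p_c4) * em.d13c_c3 + p_c4 * em.d13c_c4
        d13c_en = d13c_diet + em.enamel_diet_spacing
        d15n = (1 - p_mar) * em.d15n_terrestrial[0] + p_mar * em.d15n_marine[0]
        d13c_col = (1 - p_mar) * em.d13c_terrestrial[0] + p_mar * em.d13c_marine[0]
        records[iid] = {
            "d13c_en": d13c_en + rng.normal(0, noise_sd) if noise_sd else d13c_en,
            "d15n_col": d15n + rng.normal(0, noise_sd) if noise_sd else d15n,
            "d13c_col": d13c_col + rng.normal(0, noise_sd) if noise_sd else d13c_col,
        }
    return records


# ---------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------

def cao_family_pedigree() -> Pedigree:
    """The default four-generation burial-group pedigree fixture.

    Six sampled individuals (B1-B4 plus the two sacrificed juveniles B1s,
    B3s) and five latent relatives: B4 is the maternal grandfather of the
    full siblings B1, B2 and B3; B1s is B1's child; B3s is B2's child.
    Mitochondrial lineage mtD-1 runs through the sampled matriline; B3s
    carries mtD-2 from her unsampled mother.
    """
    return Pedigree(
        [
            Individual("B4", "M", None, None, 436, 22, "mtA-1", True),
            Individual("W4", "F", None, None, 438, None, "mtD-1", False),
            Individual("P1", "F", "W4", "B4", 456, None, "mtD-1", False),
            Individual("F1", "M", None, None, 452, None, "mtB-1", False),
            Individual("B1", "M", "P1", "F1", 472, 28, "mtD-1", True),
            Individual("B3", "F", "P1", "F1", 473, 27, "mtD-1", True),
            Individual("B2", "M", "P1", "F1", 475, 25, "mtD-1", True),
            Individual("M1s", "F", None, None, 470, None, "mtD-1", False),
            Individual("B1s", "M", "M1s", "B1", 487, 13, "mtD-1", True),
            Individual("M3s", "F", None, None, 471, None, "mtD-2", False),
            Individual("B3s", "F", "M3s", "B2", 487, 13, "mtD-2", True),
        ]
    )


DEPTH_PRESETS = {
    # emulates the study's coverage spread (0.01-1.2x)
    "study": {"B1": 1.2, "B2": 0.02, "B3": 0.4, "B4": 0.9, "B1s": 0.6, "B3s": 0.05},
    # balanced low coverage for end-to-end pipeline demonstrations
    "pipeline": {"B1": 1.2, "B2": 0.3, "B3": 0.9, "B4": 1.0, "B1s": 0.8, "B3s": 0.35},
    # uniform deep pseudohaploid data for recovery experiments
    "high": {"B1": 1.2, "B2": 1.2, "B3": 1.2, "B4": 1.2, "B1s": 1.2, "B3s": 1.2},
}

# Point diet estimates for the six burials (marine fraction, sd): the
# fractions used when simulating determinations in the study layout.
STUDY_MARINE_FRACS = {
    "B1": (0.508, 0.21),
    "B1s": (0.374, 0.21),
    "B2": (0.707, 0.21),
    "B3": (0.447, 0.235),
    "B3s": (0.303, 0.18),
    "B4": (0.645, 0.21),
}

# Bone collagen integrates over roughly the last decades of life; teeth form
# in childhood.  Tissue-formation ages used for the simulated human dates.
STUDY_TISSUE_AGES = {
    "B1": 18.0,
    "B1s": 8.0,
    "B2": 15.0,
    "B3": 17.0,
    "B3s": 8.0,
    "B4": 14.0,
}


def second_cousin_pedigree() -> Pedigree:
    """Pedigree whose proband X is the child of second cousins (F = 1/64)."""
    inds = [
        Individual("GGf", "M", sampled=False),
        Individual("GGm", "F", sampled=False),
        Individual("A1", "M", "GGm", "GGf", sampled=False),
        Individual("A2", "F", "GGm", "GGf", sampled=False),
        Individual("A1w", "F", sampled=False),
        Individual("A2h", "M", sampled=False),
        Individual("C1", "M", "A1w", "A1", sampled=False),
        Individual("C2", "F", "A2", "A2h", sampled=False),
        Individual("C1w", "F", sampled=False),
        Individual("C2h", "M", sampled=False),
        Individual("D1", "M", "C1w", "C1", sampled=False),
        Individual("D2", "F", "C2", "C2h", sampled=False),
        Individual("X", "M", "D2", "D1", sampled=True),
    ]
    return Pedigree(inds)
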