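import itertools

import numpy as np
import pytest

from paleokin import pedigree as pm, synthetic
from paleokin.genotype_io import GenotypePanel, SNPPanel


def toy_snp_panel(n, chrom=None, cm=None):
    rng = np.random.default_rng(42)
    return SNPPanel(
        ids=[f"s{i}" for i in range(n)],
        chrom=chrom if chrom is not None else ["1"] * n,
        cm=cm if cm is not None else np.linspace(0.0, 100.0, n),
        bp=np.arange(1, n + 1) * 1000,
        ref=["A"] * n,
        alt=["G"] * n,
    )


def panel_from_matrix(geno, pseudohaploid=True, **kw):
    geno = np.asarray(geno, dtype=np.int8)
    n_ind, n_snp = geno.shape
    return GenotypePanel(
        snp=toy_snp_panel(n_snp, **kw),
        genotypes=geno,
        ids=[f"I{i}" for i in range(n_ind)],
        pseudohaploid=pseudohaploid,
    )


@pytest.fixture(scope="session")
def freqs_20k():
    return synthetic.draw_frequencies(20_000, (0.5, 0.5), seed=11)


@pytest.fixture(scope="session")
def freqs_100k():
    return synthetic.draw_frequencies(100_000, (0.5, 0.5), seed=11)


@pytest.fixture(scope="session")
def cao_pedigree():
    return synthetic.cao_family_pedigree()


def perfect_evidence(ped, birth_halfwidth=10.0, type_margin=10.0):
    """EvidenceSet read directly off a true pedigree (no noise)."""
    focal = [i.id for i in ped if i.sampled]
    inds = {}
    for iid in focal:
        ind = ped.members[iid]
        biv = None
        if ind.birth_year is not None:
            biv = (ind.birth_year - birth_halfwidth, ind.birth_year + birth_halfwidth)
        inds[iid] = pm.IndividualEvidence(
            sex=ind.sex,
            age_at_death=ind.age_at_death,
            mt_lineage=ind.mt_lineage,
            birth_interval=biv,
        )
    lbl = {0: "identical", 1: "1st", 2: "2nd", 3: "3rd"}
    pairs = {}
    for a, b in itertools.combinations(focal, 2):
        d = ped.degree(a, b)
        pe = pm.PairEvidence(degree=lbl.get(d, "unrelated"))
        if d == 1:
            po = b in ped.parents(a) or a in ped.parents(b)
            pe.first_degree_type = "parent-offspring" if po else "sibling"
            pe.type_margin = type_margin
        pairs[frozenset((a, b))] = pe
    return pm.EvidenceSet(inds, pairs)
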