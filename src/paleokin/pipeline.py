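"""End-to-end orchestration over the simulated burial-group study.

Glue between the modules: simulate the panel, run all kinship estimators,
fuse consensus calls, assemble the evidence set, search pedigrees, and run
the chronological model.  The command line interface is a thin wrapper
around these functions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import chronology, kinship, pedigree as ped_mod, synthetic, uniparental
from .genotype_io import GenotypePanel
from .pedigree import (
    EvidenceSet,
    IndividualEvidence,
    PairEvidence,
    Pedigree,
)
from .synthetic import AlleleFrequencySet, ReadCounts

__all__ = [
    "StudySimulation",
    "simulate_study",
    "kinship_analysis",
    "evidence_from_analysis",
    "run_chronology",
    "fig_tree_matches",
]


@dataclass
class StudySimulation:
    pedigree: Pedigree
    freqs: AlleleFrequencySet
    truth: synthetic.DiploidGenotypes
    reads: ReadCounts
    panel: GenotypePanel
    unrelated_ids: list[str]
    twin_pair: Optional[tuple[str, str]] = None


def simulate_study(
    n_snps: int = 100_000,
    depths: Optional[dict[str, float]] = None,
    seed: int = 0,
    n_unrelated: int = 4,
    twin_of: Optional[str] = "B1",
    obs_model: Optional[synthetic.ObservationModel] = None,
    freqs: Optional[AlleleFrequencySet] = None,
    pedigree: Optional[Pedigree] = None,
    unrelated_depth: float = 1.2,
) -> StudySimulation:
    """Simulate the full burial-group observation.

    Besides the six sampled burials, ``n_unrelated`` unrelated reference
    individuals (deep pseudohaploid data) are simulated to anchor the PMR
    normalization baseline, plus optionally an independent re-observation of
    one individual's genome (an 'identical' pair).
    """
    ped = pedigree or synthetic.cao_family_pedigree()
    depths = dict(depths or synthetic.DEPTH_PRESETS["high"])
    if freqs is None:
        freqs = synthetic.draw_frequencies(n_snps, (0.5, 0.5), seed=seed + 101)
    model = obs_model or synthetic.ObservationModel()

    inds = [i for i in ped]
    extra_ids = [f"U{k + 1}ref" for k in range(n_unrelated)]
    for eid in extra_ids:
        inds.append(
            ped_mod.Individual(eid, "M", sampled=True, birth_year=None)
        )
        depths.setdefault(eid, unrelated_depth)
    full = Pedigree(inds, validate=False)
    truth = synthetic.gene_drop(full, freqs, seed=seed)

    sampled = [i.id for i in ped if i.sampled] + extra_ids
    twin_pair = None
    reads = synthetic.degrade_to_reads(
        truth, model, seed=seed + 1, depths=depths, individuals=sampled
    )
    if twin_of is not None:
        twin_id = f"{twin_of}twin"
        twin_reads = synthetic.degrade_to_reads(
            truth, model, seed=seed + 2,
            depths={twin_of: depths.get(twin_of, model.mean_depth)},
            individuals=[twin_of],
        )
        reads = ReadCounts(
            ids=reads.ids + [twin_id],
            depth=np.vstack([reads.depth, twin_reads.depth]),
            alt=np.vstack([reads.alt, twin_reads.alt]),
            freqs=reads.freqs,
        )
        twin_pair = (twin_of, twin_id)
    snp = freqs.snp_panel(np.random.default_rng(7))
    sexes = []
    for iid in reads.ids:
        if iid in ped:
            sexes.append(ped.members[iid].sex)
        elif twin_pair and iid == twin_pair[1]:
            sexes.append(ped.members[twin_pair[0]].sex)
        else:
            sexes.append("M")
    panel = synthetic.pseudohaploid_call(reads, seed=seed + 3, snp=snp, sexes=sexes)
    return StudySimulation(
        pedigree=ped, freqs=freqs, truth=truth, reads=reads, panel=panel,
        unrelated_ids=extra_ids, twin_pair=twin_pair,
    )


@dataclass
class KinshipAnalysis:
    pairs: list[kinship.PairEstimate]
    consensus: dict[frozenset, kinship.ConsensusCall]
    baseline: float


def kinship_analysis(
    sim_or_panel,
    reads: Optional[ReadCounts] = None,
    freqs: Optional[AlleleFrequencySet] = None,
    unrelated_ids: Optional[set] = None,
    focal_ids: Optional[list[str]] = None,
    min_overlap: int = 2000,
    window_cm: float = 10.0,
    hmm_window_cm: float = 20.0,
    gl_error: float = 0.01,
    max_ml_sites: int = 60_000,
) -> KinshipAnalysis:
    """All pairwise estimators plus consensus for a panel.

    PMR degrees (normalized by the median PMR of the designated unrelated
    reference pairs), ML k-coefficient degrees from read-level genotype
    likelihoods, and the sibling/parent-offspring HMM for 1st-degree pairs.
    """
    if isinstance(sim_or_panel, StudySimulation):
        panel = sim_or_panel.panel
        reads = sim_or_panel.reads
        freqs = sim_or_panel.freqs
        if unrelated_ids is None:
            unrelated_ids = set(sim_or_panel.unrelated_ids)
    else:
        panel = sim_or_panel
    focal = focal_ids or panel.ids
    pairs = []
    for a, b in itertools.combinations(focal, 2):
        pmr, n, se = kinship.pairwise_mismatch_rate(panel, a, b, window_cm)
        pairs.append(
            kinship.PairEstimate(pair=(a, b), n_overlap=n, pmr=pmr, pmr_se=se)
        )
    if unrelated_ids and len(unrelated_ids) >= 2:
        pairs = kinship.normalize_pmr(
            pairs, "median-of-unrelated", unrelated_ids=set(unrelated_ids)
        )
    elif freqs is not None:
        pairs = kinship.normalize_pmr(
            pairs, "explicit-baseline",
            baseline=kinship.expected_pmr_baseline(freqs),
        )
    else:
        pairs = kinship.normalize_pmr(pairs, "median-of-unrelated")
    baseline = pairs[0].pmr / pairs[0].normalized_pmr if pairs else float("nan")

    pmr_calls: dict[frozenset, tuple[str, float]] = {}
    for p in pairs:
        call = kinship.classify_degree(p, min_overlap=min_overlap)
        p.degree_call = call
        pmr_calls[frozenset(p.pair)] = (call, 1.0)

    ml_calls: dict[frozenset, tuple[str, float]] = {}
    if reads is not None and freqs is not None:
        gls = kinship.genotype_likelihoods(reads, error=gl_error)
        ridx = {iid: k for k, iid in enumerate(reads.ids)}
        for p in pairs:
            a, b = p.pair
            if a not in ridx or b not in ridx:
                continue
            res = kinship.ml_k_coefficients(
                gls[ridx[a]], gls[ridx[b]], freqs, max_sites=max_ml_sites
            )
            if res.get("undetermined"):
                ml_calls[frozenset(p.pair)] = ("undetermined", 0.0)
                continue
            p.k0, p.k1, p.k2 = res["k0"], res["k1"], res["k2"]
            p.r, p.r_over_k0 = res["r"], res["r_over_k0"]
            call, margin = kinship.ml_degree_call(res["site_lik"])
            ml_calls[frozenset(p.pair)] = (call, min(margin / 10.0, 1.0))

    # sibling vs parent-offspring for pairs that look 1st degree
    fd_types: dict[frozenset, tuple[str, float]] = {}
    for p in pairs:
        key = frozenset(p.pair)
        looks_first = pmr_calls[key][0] == "1st" or (
            key in ml_calls and ml_calls[key][0] == "1st"
        )
        if not looks_first:
            continue
        typ, margin = kinship.first_degree_type_hmm(
            panel, p.pair[0], p.pair[1], baseline_pmr=baseline,
            window_cm=hmm_window_cm,
        )
        p.first_degree_type, p.loglik_margin = typ, margin
        if typ != "NA":
            fd_types[key] = (typ, margin)

    consensus = kinship.consensus_degrees(
        {"pmr": pmr_calls, "ml_k": ml_calls}, first_degree_types=fd_types
    )
    return KinshipAnalysis(pairs=pairs, consensus=consensus, baseline=baseline)


def evidence_from_analysis(
    analysis: KinshipAnalysis,
    individuals: dict[str, IndividualEvidence],
    focal_ids: Optional[list[str]] = None,
) -> EvidenceSet:
    focal = set(focal_ids or individuals)
    pairs = {}
    for key, cc in analysis.consensus.items():
        if not key <= focal:
            continue
        pe = PairEvidence(
            degree=cc.call,
            confidence=max(cc.confidence, 0.1),
            first_degree_type=None
            if cc.first_degree_type == "NA"
            else cc.first_degree_type,
            type_margin=0.0 if np.isnan(cc.type_margin) else cc.type_margin,
        )
        pairs[key] = pe
    return EvidenceSet(
        individuals={k: v for k, v in individuals.items() if k in focal},
        pairs=pairs,
    )


def run_chronology(
    ped: Pedigree,
    deposition_year_ce: float = 500.0,
    delta_r_true: float = -270.0,
    sigma_lab: float = 20.0,
    n_context: int = 8,
    seed: int = 0,
    n_iter: int = 6000,
    n_chains: int = 2,
    marine_fracs: Optional[dict] = None,
    tissue_ages: Optional[dict] = None,
    human_ids: Optional[list[str]] = None,
):
    """Simulate the study-layout radiocarbon dataset and fit the family model.

    Five human dates plus ``n_context`` terrestrial context dates, one
    shared depositional event for all burials except B4, free deltaR.
    Returns (determinations, model, posterior).
    """
    terr, marine = chronology.synthetic_calibration_curves()
    marine_fracs = marine_fracs or synthetic.STUDY_MARINE_FRACS
    tissue_ages = tissue_ages or synthetic.STUDY_TISSUE_AGES
    human_ids = human_ids or ["B1", "B1s", "B2", "B3s", "B4"]
    dets = synthetic.simulate_c14(
        ped,
        {k: v for k, v in tissue_ages.items() if k in human_ids},
        marine_fracs,
        delta_r_true,
        terr,
        marine,
        sigma_lab=sigma_lab,
        seed=seed,
    )
    dets += synthetic.simulate_context_dates(
        deposition_year_ce, n_context, terr, sigma_lab=sigma_lab, seed=seed + 9
    )
    ages = {}
    for iid in set(human_ids) | {"B3"}:
        a = ped.members[iid].age_at_death
        ages[iid] = (max(a - 3, 1.0), a + 3)
    deposition_members = {"B1", "B1s", "B2", "B3", "B3s"}
    model = chronology.build_family_model(
        dets,
        ped,
        terr,
        marine,
        ages_at_death=ages,
        deposition_members=deposition_members,
    )
    post = chronology.sample_posterior(
        model, n_iter=n_iter, n_chains=n_chains, seed=seed + 33
    )
    return dets, model, post


def fig_tree_matches(candidate: Pedigree, reference: Pedigree = None) -> bool:
    """Does a candidate pedigree realize the reconstructed family topology?

    Checks the kinship pattern over the six sampled burials: B1/B2/B3 full
    siblings, B1 the parent of B1s, B4 a 2nd-degree ancestor-side relative
    of the siblings, and B3s a 2nd-degree relative of B3 via B2 or an
    unsampled sibling.
    """
    want = reference or synthetic.cao_family_pedigree()
    ids = [i.id for i in want if i.sampled]
    for a, b in itertools.combinations(ids, 2):
        if candidate.degree(a, b) != want.degree(a, b):
            return False
    mo, fa = candidate.parents("B1s")
    if "B1" not in (mo, fa):
        return False
    # B1 and B3 siblings sharing both parents
    if set(candidate.parents("B1")) != set(candidate.parents("B3")):
        return False
    return True
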