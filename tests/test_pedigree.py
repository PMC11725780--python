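import itertools

import numpy as np
import pytest

from paleokin import pedigree as pm
from paleokin.pedigree import (
    EvidenceSet,
    Individual,
    IndividualEvidence,
    InvalidPedigreeError,
    PairEvidence,
    Pedigree,
    degree_from_phi,
    enumerate_candidates,
    pedigree_kinship,
    score_candidates,
)

from conftest import perfect_evidence


def montecarlo_kinship(ped, a, b, n=100_000, seed=0):
    """Single-locus gene-dropping oracle: P(two random alleles are IBD)."""
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    alleles = {}
    label = 0
    for iid in order:
        mo, fa = ped.parents(iid)
        hap = np.empty((n, 2), dtype=np.int64)
        for h, parent in enumerate((mo, fa)):
            if parent is None:
                hap[:, h] = label
                label += 1
            else:
                pick = rng.integers(2, size=n)
                hap[:, h] = alleles[parent][np.arange(n), pick]
        alleles[iid] = hap
    ai = alleles[a][np.arange(n), rng.integers(2, size=n)]
    bj = alleles[b][np.arange(n), rng.integers(2, size=n)]
    return float((ai == bj).mean())


class TestKinshipAlgebra:
    def test_parent_child(self):
        ped = Pedigree(
            [
                Individual("M", "F"),
                Individual("C", "M", mother="M"),
            ]
        )
        assert ped.kinship("M", "C") == 0.25
        assert ped.degree("M", "C") == 1

    def test_half_sibs(self):
        ped = Pedigree(
            [
                Individual("M", "F"),
                Individual("F1", "M"),
                Individual("F2", "M"),
                Individual("A", "M", mother="M", father="F1"),
                Individual("B", "F", mother="M", father="F2"),
            ]
        )
        assert ped.kinship("A", "B") == 0.125
        assert ped.degree("A", "B") == 2

    def test_inbred_self_kinship(self):
        # full-sib mating: offspring F = 1/4
        ped = Pedigree(
            [
                Individual("M", "F"),
                Individual("F0", "M"),
                Individual("S", "F", mother="M", father="F0"),
                Individual("B", "M", mother="M", father="F0"),
                Individual("X", "M", mother="S", father="B"),
            ]
        )
        assert ped.inbreeding("X") == 0.25
        assert ped.kinship("X", "X") == 0.5 * 1.25

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_gene_dropping_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng)
        ids = ped.ids
        pairs = list(itertools.combinations(ids, 2))
        sel = [pairs[i] for i in rng.choice(len(pairs), size=4, replace=False)]
        for a, b in sel:
            phi = ped.kinship(a, b)
            n = 100_000
            mc = montecarlo_kinship(ped, a, b, n=n, seed=seed + 10)
            se = max(np.sqrt(phi * (1 - phi) / n), 1e-4)
            assert abs(mc - phi) < max(3 * se, 0.004)

    def test_degree_bands(self):
        assert degree_from_phi(0.25) == 1
        assert degree_from_phi(0.125) == 2
        assert degree_from_phi(0.0625) == 3
        assert degree_from_phi(0.5) == 0
        assert degree_from_phi(0.0) is None

    def test_pedigree_kinship_operation(self):
        ped = Pedigree(
            [
                Individual("M", "F"),
                Individual("C", "F", mother="M"),
                Individual("G", "M", mother="C"),
            ]
        )
        out = pedigree_kinship(ped)
        assert out[frozenset(("M", "G"))] == (0.125, 2)

    def test_invalid_sex_parent(self):
        with pytest.raises(InvalidPedigreeError, match="sex"):
            Pedigree(
                [
                    Individual("A", "M"),
                    Individual("C", "F", mother="A"),
                ]
            )


def random_pedigree(rng, n_extra=4):
    """Random 3-generation pedigree (10-ish nodes), valid by construction."""
    inds = [
        Individual("gm1", "F"), Individual("gf1", "M"),
        Individual("gm2", "F"), Individual("gf2", "M"),
    ]
    mid = []
    for k in range(rng.integers(2, 4)):
        cpl = rng.integers(2)
        sex = "MF"[rng.integers(2)]
        iid = f"p{k}"
        inds.append(
            Individual(iid, sex, mother=f"gm{cpl + 1}", father=f"gf{cpl + 1}")
        )
        mid.append((iid, sex))
    males = [i for i, s in mid if s == "M"] + ["gf2"]
    females = [i for i, s in mid if s == "F"] + ["gm2"]
    for k in range(n_extra):
        mo = females[rng.integers(len(females))]
        fa = males[rng.integers(len(males))]
        mo_of = {i.id: i.mother for i in inds}
        fa_of = {i.id: i.father for i in inds}
        if mo_of.get(fa) == mo_of.get(mo) and mo_of.get(fa) is not None:
            continue  # avoid full-sib matings for simplicity
        if fa == fa_of.get(mo) or mo == mo_of.get(fa):
            continue
        inds.append(Individual(f"c{k}", "MF"[rng.integers(2)], mother=mo, father=fa))
    return Pedigree(inds)


class TestEnumeration:
    def two_person_evidence(self, ages, deaths, degree="1st", tp=None):
        inds = {
            "A": IndividualEvidence(
                sex="F", age_at_death=ages[0],
                death_interval=(deaths[0] - 2, deaths[0] + 2),
            ),
            "B": IndividualEvidence(
                sex="M", age_at_death=ages[1],
                death_interval=(deaths[1] - 2, deaths[1] + 2),
            ),
        }
        pe = PairEvidence(degree=degree)
        if tp:
            pe.first_degree_type = tp
            pe.type_margin = 5.0
        return EvidenceSet(inds, {frozenset(("A", "B")): pe})

    def test_adult_and_child_po_or_sib(self):
        # ages 30 and 5, same death date: parent-offspring with the elder as
        # parent is feasible; siblings also (birth gap 25 < 45)
        ev = self.two_person_evidence((30, 5), (500, 500))
        cands, info = enumerate_candidates(ev, max_latent=2)
        kinds = set()
        for ped in cands:
            mo, fa = ped.parents("B")
            if "A" in (mo, fa):
                kinds.add("po")
            elif set(ped.parents("A")) & set(ped.parents("B")) - {None}:
                kinds.add("sib")
        assert "po" in kinds and "sib" in kinds
        # the child cannot be the parent of the adult
        for ped in cands:
            assert "B" not in ped.parents("A")

    def test_large_birth_gap_excludes_siblings(self):
        # 43-year birth gap: outside the shared-mother fertile window
        # (<= 38 y), but fine for parent-offspring
        ev = self.two_person_evidence((48, 5), (500, 500))
        cands, _ = enumerate_candidates(ev, max_latent=2)
        assert cands
        po_seen = False
        for ped in cands:
            shared = set(ped.parents("A")) & set(ped.parents("B")) - {None}
            assert not shared  # no full siblings
            po_seen = po_seen or "A" in ped.parents("B")
        assert po_seen

    def test_contradictory_evidence_conflict(self):
        inds = {
            x: IndividualEvidence(sex="M", age_at_death=30,
                                  death_interval=(498, 502))
            for x in "ABC"
        }
        pairs = {
            frozenset(("A", "B")): PairEvidence("1st"),
            frozenset(("B", "C")): PairEvidence("1st"),
            frozenset(("A", "C")): PairEvidence("unrelated"),
        }
        cands, info = enumerate_candidates(EvidenceSet(inds, pairs), max_latent=3)
        # A-B 1st and B-C 1st force A-C relatedness above 'unrelated' unless
        # both links are parent-offspring through B; with equal tight death
        # dates and equal ages, the parent option dies on the age gap
        assert cands == [] and info["conflicts"]

    def test_true_pedigree_recovered_from_correct_degrees(self):
        """The generating pedigree's kinship structure is in the search output."""
        hits = 0
        n_ped = 8
        for seed in range(n_ped):
            rng = np.random.default_rng(200 + seed)
            full = random_pedigree(rng)
            sampled = [
                i.id for i in full
                if i.id.startswith(("p", "c")) and rng.random() < 0.9
            ][:7]
            if len(sampled) < 4:
                hits += 1  # trivially small draw; skip as success
                continue
            truth = Pedigree(
                [
                    Individual(
                        i.id, i.sex, i.mother, i.father,
                        sampled=i.id in sampled,
                    )
                    for i in full
                ]
            )
            ev_inds = {
                iid: IndividualEvidence(sex=truth.members[iid].sex)
                for iid in sampled
            }
            lbl = {0: "identical", 1: "1st", 2: "2nd", 3: "3rd"}
            ev_pairs = {}
            for a, b in itertools.combinations(sampled, 2):
                d = truth.degree(a, b)
                ev_pairs[frozenset((a, b))] = PairEvidence(
                    lbl.get(d, "unrelated")
                )
            cands, info = enumerate_candidates(
                EvidenceSet(ev_inds, ev_pairs), max_latent=4, cap=250_000
            )
            want = {
                frozenset(p): truth.kinship(*p)
                for p in itertools.combinations(sampled, 2)
            }
            for cand in cands:
                got = {
                    frozenset(p): cand.kinship(*p)
                    for p in itertools.combinations(sampled, 2)
                }
                if all(abs(got[k] - want[k]) < 1e-9 for k in want):
                    hits += 1
                    break
        assert hits == n_ped

    def test_search_order_invariance_of_scores(self):
        ev = self.two_person_evidence((30, 5), (500, 500), tp="parent-offspring")
        cands, _ = enumerate_candidates(ev, max_latent=2)
        s1 = score_candidates(cands, ev)
        s2 = score_candidates(list(reversed(cands)), ev)
        assert sorted(round(s.score, 9) for s in s1) == sorted(
            round(s.score, 9) for s in s2
        )
        assert s1[0].score == s2[0].score


class TestScoring:
    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            score_candidates([], EvidenceSet({}, {}))

    def test_sibling_outranks_parent_when_births_cooccur(self):
        """Coeval modeled births favour a sibling over a parent placement."""
        inds = {
            "A": IndividualEvidence(sex="M", age_at_death=28,
                                    birth_interval=(465, 490)),
            "B": IndividualEvidence(sex="M", age_at_death=25,
                                    birth_interval=(470, 492)),
        }
        ev = EvidenceSet(inds, {frozenset(("A", "B")): PairEvidence("1st")})
        sib = Pedigree(
            [
                Individual("U1", "F", sampled=False),
                Individual("U2", "M", sampled=False),
                Individual("A", "M", "U1", "U2", age_at_death=28),
                Individual("B", "M", "U1", "U2", age_at_death=25),
            ]
        )
        par = Pedigree(
            [
                Individual("U1", "F", sampled=False),
                Individual("B", "M", age_at_death=25),
                Individual("A", "M", "U1", "B", age_at_death=28),
            ]
        )
        scored = score_candidates([sib, par], ev)
        by_id = {len(s.pedigree): s for s in scored}
        assert by_id[4].score > by_id[3].score  # sibling variant wins

    def test_grandchild_vetoed_by_generational_gap(self):
        """A 2nd-degree juvenile cannot be the grandchild of a young adult."""
        inds = {
            "G": IndividualEvidence(sex="F", age_at_death=28,
                                    birth_interval=(468, 478)),
            "K": IndividualEvidence(sex="F", age_at_death=13,
                                    birth_interval=(484, 490)),
        }
        ev = EvidenceSet(inds, {frozenset(("G", "K")): PairEvidence("2nd")})
        grandchild = Pedigree(
            [
                Individual("G", "F", age_at_death=28),
                Individual("U1", "M", sampled=False),
                Individual("L", "F", "G", "U1", sampled=False),
                Individual("U2", "M", sampled=False),
                Individual("K", "F", "L", "U2", age_at_death=13),
            ]
        )
        scored = score_candidates([grandchild], ev)
        assert scored[0].vetoed
        # and the enumeration never emits it
        cands, _ = enumerate_candidates(ev, max_latent=3)
        for ped in cands:
            anc = pm._sampled_ancestor_gaps(ped, ["G", "K"])
            assert ("G", "K", 2) not in anc

    def test_mt_lineage_veto(self):
        inds = {
            "A": IndividualEvidence(sex="F", mt_lineage="mt1"),
            "B": IndividualEvidence(sex="F", mt_lineage="mt2"),
        }
        ev = EvidenceSet(inds, {frozenset(("A", "B")): PairEvidence("1st")})
        sibs = Pedigree(
            [
                Individual("U1", "F", sampled=False),
                Individual("U2", "M", sampled=False),
                Individual("A", "F", "U1", "U2"),
                Individual("B", "F", "U1", "U2"),
            ]
        )
        scored = score_candidates([sibs], ev)
        assert scored[0].vetoed and scored[0].score == -np.inf

    def test_ties_reported(self):
        inds = {
            "A": IndividualEvidence(sex="M"),
            "B": IndividualEvidence(sex="M"),
        }
        ev = EvidenceSet(inds, {frozenset(("A", "B")): PairEvidence("1st")})
        sib = Pedigree(
            [
                Individual("U1", "F", sampled=False),
                Individual("U2", "M", sampled=False),
                Individual("A", "M", "U1", "U2"),
                Individual("B", "M", "U1", "U2"),
            ]
        )
        sib2 = Pedigree(
            [
                Individual("V1", "F", sampled=False),
                Individual("V2", "M", sampled=False),
                Individual("A", "M", "V1", "V2"),
                Individual("B", "M", "V1", "V2"),
            ]
        )
        scored = score_candidates([sib, sib2], ev)
        assert scored[0].tied_with == [1] and scored[1].tied_with == [0]
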