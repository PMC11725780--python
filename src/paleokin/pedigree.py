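"""Pedigree graphs, kinship algebra, and evidence-constrained pedigree search.

A pedigree is a directed acyclic graph of individuals with parent edges.
Kinship coefficients are computed by the classic recursive decomposition
(phi(i,j) = mean of phi(i, parents of j) for the individual of greater
generation depth), and relatedness degrees follow the usual dyadic bands
(parent/child and full siblings phi=1/4 -> 1st degree, phi=1/8 -> 2nd,
phi=1/16 -> 3rd).

The search half of the module enumerates small pedigrees -- including
unsampled ("latent") individuals -- compatible with a set of pairwise degree
estimates, sexes, ages, mitochondrial-lineage labels and modeled birth-date
intervals, and scores candidates with an additive log-score.  This is an
explicit constraint-satisfaction rendering of the multi-evidence family-tree
reconstruction used for small ancient-DNA burial groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "Individual",
    "Pedigree",
    "InvalidPedigreeError",
    "degree_from_phi",
    "pedigree_kinship",
    "EvidenceSet",
    "PairEvidence",
    "enumerate_candidates",
    "score_candidates",
    "ScoredPedigree",
    "read_pedigree",
    "write_pedigree",
]

DEGREE_LABELS = {0: "identical", 1: "1st", 2: "2nd", 3: "3rd"}

# Minimum / maximum parental age at a child's birth, in years.  The lower
# bound is biological; the upper bound is a pragmatic archaeological window
# (female menopause; configurable by callers).
PARENT_AGE_MIN = 12.0
PARENT_AGE_MAX = 50.0


class InvalidPedigreeError(ValueError):
    """Raised for cyclic pedigrees or sex-inconsistent parent assignments."""


@dataclass
class Individual:
    id: str
    sex: str  # 'M' or 'F'
    mother: Optional[str] = None
    father: Optional[str] = None
    birth_year: Optional[float] = None  # calendar year CE
    age_at_death: Optional[float] = None  # years
    mt_lineage: Optional[str] = None
    sampled: bool = True

    @property
    def death_year(self) -> Optional[float]:
        if self.birth_year is None or self.age_at_death is None:
            return None
        return self.birth_year + self.age_at_death


class Pedigree:
    """A collection of individuals with validated parent edges."""

    def __init__(self, individuals: Iterable[Individual], validate: bool = True):
        self.members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.members:
                raise InvalidPedigreeError(f"duplicate individual id {ind.id!r}")
            self.members[ind.id] = ind
        if validate:
            self.validate()
        self._phi_cache: dict[frozenset, float] = {}

    def __contains__(self, iid: str) -> bool:
        return iid in self.members

    def __iter__(self):
        return iter(self.members.values())

    def __len__(self):
        return len(self.members)

    @property
    def ids(self) -> list[str]:
        return list(self.members)

    @property
    def sampled_ids(self) -> list[str]:
        return [i.id for i in self if i.sampled]

    def parents(self, iid: str) -> tuple[Optional[str], Optional[str]]:
        ind = self.members[iid]
        return ind.mother, ind.father

    def children(self, iid: str) -> list[str]:
        return [i.id for i in self if iid in (i.mother, i.father)]

    def founders(self) -> list[str]:
        return [i.id for i in self if i.mother is None and i.father is None]

    # ---- validation -------------------------------------------------

    def validate(self) -> None:
        for ind in self:
            for pid, want_sex, role in (
                (ind.mother, "F", "mother"),
                (ind.father, "M", "father"),
            ):
                if pid is None:
                    continue
                if pid not in self.members:
                    raise InvalidPedigreeError(
                        f"{ind.id}: {role} {pid!r} not in pedigree"
                    )
                if self.members[pid].sex != want_sex:
                    raise InvalidPedigreeError(
                        f"{ind.id}: {role} {pid} has sex "
                        f"{self.members[pid].sex!r}"
                    )
            if ind.sex not in ("M", "F"):
                raise InvalidPedigreeError(f"{ind.id}: sex must be 'M' or 'F'")
        self.topological_order()  # raises on cycles
        for ind in self:
            for pid in (ind.mother, ind.father):
                if pid is None:
                    continue
                pb = self.members[pid].birth_year
                if ind.birth_year is not None and pb is not None:
                    if ind.birth_year < pb + PARENT_AGE_MIN:
                        raise InvalidPedigreeError(
                            f"{ind.id}: born {ind.birth_year} less than "
                            f"{PARENT_AGE_MIN} y after parent {pid} ({pb})"
                        )
            if ind.mother is not None:
                mlin = self.members[ind.mother].mt_lineage
                if (
                    mlin is not None
                    and ind.mt_lineage is not None
                    and ind.mt_lineage != mlin
                ):
                    raise InvalidPedigreeError(
                        f"{ind.id}: mt lineage {ind.mt_lineage!r} differs "
                        f"from mother's {mlin!r}"
                    )

    def topological_order(self) -> list[str]:
        """Founders first; raises InvalidPedigreeError on cycles."""
        order: list[str] = []
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            st = state.get(iid)
            if st == 1:
                return
            if st == 0:
                raise InvalidPedigreeError(
                    "pedigree contains a cycle through " + " -> ".join(stack)
                )
            state[iid] = 0
            for pid in self.parents(iid):
                if pid is not None:
                    visit(pid, stack + [iid])
            state[iid] = 1
            order.append(iid)

        for iid in self.members:
            visit(iid, [])
        return order

    # ---- kinship algebra --------------------------------------------

    def _depth(self, iid: str, memo: dict[str, int]) -> int:
        if iid in memo:
            return memo[iid]
        ps = [p for p in self.parents(iid) if p is not None]
        d = 0 if not ps else 1 + max(self._depth(p, memo) for p in ps)
        memo[iid] = d
        return d

    def kinship(self, a: str, b: str) -> float:
        """Kinship coefficient phi(a, b) by recursive decomposition."""
        memo_depth: dict[str, int] = {}

        def phi(i: str, j: str) -> float:
            key = frozenset((i, j))
            if key in self._phi_cache:
                return self._phi_cache[key]
            if i == j:
                m, f = self.parents(i)
                inb = phi(m, f) if (m is not None and f is not None) else 0.0
                val = 0.5 * (1.0 + inb)
            else:
                # recurse on the individual with greater generation depth
                if self._depth(i, memo_depth) > self._depth(j, memo_depth):
                    i, j = j, i
                m, f = self.parents(j)
                val = 0.0
                if m is not None:
                    val += 0.5 * phi(i, m)
                if f is not None:
                    val += 0.5 * phi(i, f)
            self._phi_cache[key] = val
            return val

        return phi(a, b)

    def inbreeding(self, iid: str) -> float:
        m, f = self.parents(iid)
        if m is None or f is None:
            return 0.0
        return self.kinship(m, f)

    def kinship_matrix(self, ids: Optional[list[str]] = None):
        ids = ids if ids is not None else self.ids
        return {
            frozenset((a, b)): self.kinship(a, b)
            for a, b in itertools.combinations(ids, 2)
        }

    def degree(self, a: str, b: str) -> Optional[int]:
        """Relatedness degree; None for phi == 0 (unrelated)."""
        return degree_from_phi(self.kinship(a, b))

    # ---- matrilines --------------------------------------------------

    def matriline_root(self, iid: str) -> str:
        seen = set()
        while True:
            if iid in seen:
                raise InvalidPedigreeError("maternal cycle")
            seen.add(iid)
            m = self.members[iid].mother
            if m is None:
                return iid
            iid = m


def degree_from_phi(phi: float) -> Optional[int]:
    """Map a kinship coefficient to a relatedness degree.

    degree d corresponds to phi = 2**-(d+1); band boundaries sit at the
    geometric midpoints (factor sqrt(2)).  Returns 0 for identical
    (phi ~ 1/2), None for unrelated (phi below the 4th-degree band floor).
    """
    if phi <= 0:
        return None
    d = round(-math.log2(4.0 * phi)) + 1
    return max(int(d), 0)


def pedigree_kinship(pedigree: Pedigree, ids: Optional[list[str]] = None):
    """Pairwise kinship coefficients and degrees for a pedigree.

    Returns dict frozenset{a,b} -> (phi, degree); the public operation
    wrapper around :meth:`Pedigree.kinship`.
    """
    ids = ids if ids is not None else pedigree.ids
    out = {}
    for a, b in itertools.combinations(ids, 2):
        phi = pedigree.kinship(a, b)
        out[frozenset((a, b))] = (phi, degree_from_phi(phi))
    return out


# ---------------------------------------------------------------------
# pedigree text format (one row per individual, tab separated)
# ---------------------------------------------------------------------

_PED_COLS = "id sex mother father birth_year age_at_death mt_lineage sampled".split()


def write_pedigree(pedigree: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PED_COLS) + "\n")
        for ind in pedigree:
            row = [
                ind.id,
                ind.sex,
                ind.mother or "NA",
                ind.father or "NA",
                "NA" if ind.birth_year is None else f"{ind.birth_year:g}",
                "NA" if ind.age_at_death is None else f"{ind.age_at_death:g}",
                ind.mt_lineage or "NA",
                "1" if ind.sampled else "0",
            ]
            fh.write("\t".join(row) + "\n")


def read_pedigree(path) -> Pedigree:
    inds = []
    with open(path) as fh:
        header = fh.readline().split()
        if header != _PED_COLS:
            raise ValueError(f"unexpected pedigree header {header}")
        for line in fh:
            if not line.strip():
                continue
            (iid, sex, mo, fa, by, aad, mt, samp) = line.split("\t")
            inds.append(
                Individual(
                    id=iid,
                    sex=sex,
                    mother=None if mo == "NA" else mo,
                    father=None if fa == "NA" else fa,
                    birth_year=None if by == "NA" else float(by),
                    age_at_death=None if aad == "NA" else float(aad),
                    mt_lineage=None if mt == "NA" else mt,
                    sampled=samp.strip() == "1",
                )
            )
    return Pedigree(inds)


# ---------------------------------------------------------------------
# evidence-constrained enumeration
# ---------------------------------------------------------------------

DEGREE_CALLS = {"identical", "1st", "2nd", "3rd", "unrelated", "undetermined"}


@dataclass
class PairEvidence:
    degree: str  # one of DEGREE_CALLS
    confidence: float = 1.0
    # sibling / parent-offspring discrimination for 1st-degree pairs
    first_degree_type: Optional[str] = None  # 'sibling' | 'parent-offspring'
    type_margin: float = 0.0  # log-likelihood margin favouring that type


@dataclass
class IndividualEvidence:
    sex: str
    age_at_death: Optional[float] = None
    mt_lineage: Optional[str] = None
    birth_interval: Optional[tuple[float, float]] = None  # CE, 95% interval
    death_interval: Optional[tuple[float, float]] = None


@dataclass
class EvidenceSet:
    individuals: dict[str, IndividualEvidence]
    pairs: dict[frozenset, PairEvidence]

    def pair(self, a: str, b: str) -> PairEvidence:
        return self.pairs.get(frozenset((a, b)), PairEvidence("undetermined", 0.0))


def _phi_band(degree_call: str) -> tuple[float, float]:
    """Allowed final kinship interval for an evidence degree call."""
    centers = {"identical": 0.5, "1st": 0.25, "2nd": 0.125, "3rd": 0.0625}
    if degree_call == "undetermined":
        return (0.0, 1.0)
    if degree_call == "unrelated":
        # anything rounding to 4th degree or beyond (or phi == 0)
        return (0.0, 0.03125 * math.sqrt(2.0))
    c = centers[degree_call]
    if degree_call == "3rd":
        # 3rd degree and beyond collapse to "distant": accept phi <= band top
        return (0.0 + 1e-12, c * math.sqrt(2.0))
    return (c / math.sqrt(2.0), c * math.sqrt(2.0))


def _phi_upper(degree_call: str) -> float:
    return _phi_band(degree_call)[1]


@dataclass
class _SearchState:
    # parent assignment: id -> (mother, father) or None meaning founder;
    # absence from `decided` means not yet processed.
    parents: dict[str, tuple[Optional[str], Optional[str]]]
    decided: set[str]
    sexes: dict[str, str]
    latent: list[str]
    queue: list[str]


def _birth_interval(ev: EvidenceSet, iid: str) -> Optional[tuple[float, float]]:
    ind = ev.individuals[iid]
    if ind.birth_interval is not None:
        return ind.birth_interval
    if ind.death_interval is not None and ind.age_at_death is not None:
        lo, hi = ind.death_interval
        return (lo - ind.age_at_death, hi - ind.age_at_death)
    return None


def _gap_feasible(
    parent_iv: Optional[tuple[float, float]],
    child_iv: Optional[tuple[float, float]],
    gap: tuple[float, float] = (PARENT_AGE_MIN, PARENT_AGE_MAX),
) -> bool:
    if parent_iv is None or child_iv is None:
        return True
    lo, hi = gap
    return child_iv[1] - parent_iv[0] >= lo and child_iv[0] - parent_iv[1] <= hi


def enumerate_candidates(
    evidence: EvidenceSet,
    max_latent: int = 6,
    max_depth: int = 3,
    cap: int = 400_000,
    gap: tuple[float, float] = (PARENT_AGE_MIN, PARENT_AGE_MAX),
    max_couple_kinship: float = 0.06,
):
    """Enumerate pedigrees compatible with an evidence set.

    Every sampled pair's final pedigree degree must be compatible with its
    consensus degree call ('undetermined' is a wildcard); parent sexes are
    valid by construction; age/birth-date orderings must be feasible; and no
    maternal path may connect two sampled individuals with different mt
    lineage labels.  Latent (unsampled) individuals are created on demand up
    to ``max_latent`` and deduplicated up to isomorphism.

    Returns (candidates, info) where candidates is a list of Pedigree and
    info carries 'expansions', 'overflow' and 'conflicts'.
    """
    sampled = list(evidence.individuals)
    if len(sampled) > 8:
        raise ValueError("enumeration supports at most 8 sampled individuals")
    birth_ivs = {i: _birth_interval(evidence, i) for i in sampled}

    def sort_key(i):
        iv = birth_ivs[i]
        return (0.5 * (iv[0] + iv[1])) if iv else 0.0

    order = sorted(sampled, key=sort_key)

    results: list[Pedigree] = []
    seen_forms: set = set()
    info = {"expansions": 0, "overflow": False, "conflicts": []}

    def make_pedigree(state: _SearchState) -> Pedigree:
        inds = []
        for iid in list(state.parents):
            mo, fa = state.parents.get(iid, (None, None))
            if iid in evidence.individuals:
                ev = evidence.individuals[iid]
                inds.append(
                    Individual(
                        iid,
                        ev.sex,
                        mo,
                        fa,
                        age_at_death=ev.age_at_death,
                        mt_lineage=ev.mt_lineage,
                        sampled=True,
                    )
                )
            else:
                inds.append(
                    Individual(iid, state.sexes[iid], mo, fa, sampled=False)
                )
        return Pedigree(inds, validate=False)

    def ancestors_decided(ped_state: _SearchState, iid: str) -> bool:
        stack = [iid]
        while stack:
            x = stack.pop()
            if x not in ped_state.decided:
                return False
            mo, fa = ped_state.parents.get(x, (None, None))
            stack.extend(p for p in (mo, fa) if p is not None)
        return True

    def is_descendant(state: _SearchState, anc: str, node: str) -> bool:
        """True if `node` is an ancestor... i.e. anc appears above node? No:
        returns True when `anc` is reachable from `node` going down -- used to
        forbid choosing a descendant of `node` as its parent."""
        stack = [anc]
        while stack:
            x = stack.pop()
            if x == node:
                return True
            mo, fa = state.parents.get(x, (None, None))
            stack.extend(p for p in (mo, fa) if p is not None)
        return False

    def depth_above_sampled(state: _SearchState, iid: str) -> int:
        # min #generations from iid down to any sampled individual
        best = [99]

        def down(x, d):
            if x in evidence.individuals:
                best[0] = min(best[0], d)
                return
            for c, (mo, fa) in state.parents.items():
                if x in (mo, fa):
                    down(c, d + 1)

        down(iid, 0)
        return best[0]

    def fast_phis(parents: dict) -> dict[frozenset, float]:
        """Kinship over sampled pairs straight off the parents mapping."""
        depth: dict[str, int] = {}
        pending = list(parents)
        while pending:
            nxt = []
            for x in pending:
                ps = [p for p in parents.get(x, (None, None)) if p is not None]
                if not ps:
                    depth[x] = 0
                elif all(p in depth for p in ps):
                    depth[x] = 1 + max(depth[p] for p in ps)
                else:
                    nxt.append(x)
            if len(nxt) == len(pending):  # cycle guard
                for x in nxt:
                    depth[x] = 0
                break
            pending = nxt

        cache: dict[tuple, float] = {}

        def phi2(i, j):
            if i > j:
                i, j = j, i
            key = (i, j)
            val = cache.get(key)
            if val is not None:
                return val
            if i == j:
                m, f = parents.get(i, (None, None))
                val = 0.5 * (1.0 + (phi2(m, f) if m and f else 0.0))
            else:
                b = j if depth[i] <= depth[j] else i
                a = i if b is j else j
                m, f = parents.get(b, (None, None))
                val = 0.0
                if m is not None:
                    val += 0.5 * phi2(a, m)
                if f is not None:
                    val += 0.5 * phi2(a, f)
            cache[key] = val
            return val

        return {
            frozenset((a, b)): phi2(a, b) for a, b in sampled_pairs
        }

    sampled_pairs = list(itertools.combinations(sampled, 2))
    pair_ev = {
        frozenset(p): evidence.pair(*p) for p in sampled_pairs
    }

    def prune_or_record(state: _SearchState) -> Optional[bool]:
        """Kinship screening over sampled pairs with current assignments.

        Returns False to prune; True to continue.
        """
        phis = fast_phis(state.parents)
        decided_cache: dict[str, bool] = {}

        def decided_ok(x):
            if x not in decided_cache:
                decided_cache[x] = ancestors_decided(state, x)
            return decided_cache[x]

        for key, phi in phis.items():
            pe = pair_ev[key]
            # lower bound: adding more ancestors can only increase phi
            if phi > _phi_upper(pe.degree) + 1e-12:
                return False
            if pe.degree != "undetermined":
                a, b = key
                if decided_ok(a) and decided_ok(b):
                    lo, hi = _phi_band(pe.degree)
                    if not (lo <= phi <= hi):
                        return False
        return True

    def matrilines_ok(ped: Pedigree) -> bool:
        roots: dict[str, str] = {}
        for iid in sampled:
            roots[iid] = ped.matriline_root(iid)
        by_root: dict[str, set] = {}
        for iid, r in roots.items():
            lab = evidence.individuals[iid].mt_lineage
            if lab is None:
                continue
            by_root.setdefault(r, set()).add(lab)
        return all(len(labs) == 1 for labs in by_root.values())

    def finalize(state: _SearchState) -> None:
        ped = make_pedigree(state)
        # exact degree compatibility
        for a, b in itertools.combinations(sampled, 2):
            pe = evidence.pair(a, b)
            if pe.degree == "undetermined":
                continue
            lo, hi = _phi_band(pe.degree)
            phi = ped.kinship(a, b)
            if not (lo <= phi <= hi):
                return
        if not matrilines_ok(ped):
            return
        # age feasibility on ancestor paths between sampled individuals
        # (composing g-generation windows through latent links)
        for anc, desc, g in _sampled_ancestor_gaps(ped, sampled):
            if not _gap_feasible(
                birth_ivs.get(anc), birth_ivs.get(desc),
                (g * gap[0], g * gap[1]),
            ):
                return
        for a, b, g1, g2 in _common_ancestor_diff_windows(ped, sampled):
            if not _diff_window_feasible(
                birth_ivs.get(a), birth_ivs.get(b), g1, g2, gap
            ):
                return
        # drop pedigrees with a redundant latent founder couple (single
        # shared child, no parents): equivalent to the child being a founder
        for iid in state.latent:
            mo, fa = state.parents.get(iid, (None, None))
            if mo is not None or fa is not None:
                continue
            kids = ped.children(iid)
            if len(kids) == 1:
                child = kids[0]
                cmo, cfa = state.parents.get(child, (None, None))
                other = cfa if cmo == iid else cmo
                if other in state.latent:
                    omo, ofa = state.parents.get(other, (None, None))
                    if omo is None and ofa is None and len(ped.children(other)) == 1:
                        return
        form = canonical_form(ped, sampled)
        if form in seen_forms:
            return
        seen_forms.add(form)
        results.append(ped)

    def expand(state: _SearchState) -> None:
        if info["expansions"] >= cap:
            info["overflow"] = True
            return
        info["expansions"] += 1
        if not prune_or_record(state):
            return
        if not state.queue:
            finalize(state)
            return
        iid = state.queue[0]
        rest = state.queue[1:]
        child_iv = birth_ivs.get(iid)

        def candidates_of(sex: str) -> list[Optional[str]]:
            opts: list[Optional[str]] = []
            for other in state.parents:
                if other == iid or state.sexes[other] != sex:
                    continue
                if is_descendant(state, other, iid):
                    continue
                if other in birth_ivs and not _gap_feasible(
                    birth_ivs[other], child_iv, gap
                ):
                    continue
                if evidence.individuals.get(other) is not None:
                    ev = evidence.individuals[other]
                    if ev.age_at_death is not None and ev.age_at_death < gap[0]:
                        continue  # died a child: cannot be a parent
                opts.append(other)
            return opts

        # option 1: founder (no parents)
        st = _SearchState(
            dict(state.parents),
            set(state.decided) | {iid},
            dict(state.sexes),
            list(state.latent),
            rest,
        )
        st.parents[iid] = (None, None)
        expand(st)

        # option 2: both parents among existing nodes and/or new latents
        can_new = len(state.latent) < max_latent
        new_ok = (
            can_new
            and (iid in evidence.individuals or depth_above_sampled(state, iid) < max_depth)
        )
        mothers = candidates_of("F") + ([None] if new_ok else [])
        can_two_new = len(state.latent) + 2 <= max_latent
        for mo in mothers:
            fathers = candidates_of("M")
            if mo is None:
                fathers = fathers + ([None] if can_two_new and new_ok else [])
            else:
                fathers = fathers + ([None] if new_ok else [])
            for fa in fathers:
                if mo is not None and fa is not None:
                    # no close-kin parent couples (kinship can only grow as
                    # ancestors are added, so this prune is safe)
                    couple_phi = _phi_of_pair(state.parents, mo, fa)
                    if couple_phi > max_couple_kinship:
                        continue
                st = _SearchState(
                    dict(state.parents),
                    set(state.decided) | {iid},
                    dict(state.sexes),
                    list(state.latent),
                    list(rest),
                )
                mo_id, fa_id = mo, fa
                created = []
                if mo_id is None:
                    mo_id = f"U{len(st.latent) + 1}"
                    st.latent.append(mo_id)
                    st.sexes[mo_id] = "F"
                    st.parents[mo_id] = (None, None)
                    created.append(mo_id)
                if fa_id is None:
                    fa_id = f"U{len(st.latent) + 1}"
                    st.latent.append(fa_id)
                    st.sexes[fa_id] = "M"
                    st.parents[fa_id] = (None, None)
                    created.append(fa_id)
                st.queue.extend(created)
                st.parents[iid] = (mo_id, fa_id)
                # a latent placed in the queue is "undecided" until processed
                st.decided.discard(mo_id) if mo is None else None
                st.decided.discard(fa_id) if fa is None else None
                expand(st)

    init = _SearchState(
        parents={i: (None, None) for i in sampled},
        decided=set(),
        sexes={i: evidence.individuals[i].sex for i in sampled},
        latent=[],
        queue=list(order),
    )
    # seed parents dict keys only for existence checks; none decided yet
    expand(init)

    if not results:
        info["conflicts"].append(
            "no pedigree satisfies all determined degree calls jointly"
        )
    return results, info





def _phi_of_pair(parents: dict, a: str, b: str) -> float:
    depth: dict[str, int] = {}

    def get_depth(x):
        if x in depth:
            return depth[x]
        ps = [p for p in parents.get(x, (None, None)) if p is not None]
        d = 0 if not ps else 1 + max(get_depth(p) for p in ps)
        depth[x] = d
        return d

    cache: dict[tuple, float] = {}

    def phi2(i, j):
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in cache:
            return cache[key]
        if i == j:
            m, f = parents.get(i, (None, None))
            val = 0.5 * (1.0 + (phi2(m, f) if m and f else 0.0))
        else:
            bb = j if get_depth(i) <= get_depth(j) else i
            aa = i if bb is j else j
            m, f = parents.get(bb, (None, None))
            val = 0.0
            if m is not None:
                val += 0.5 * phi2(aa, m)
            if f is not None:
                val += 0.5 * phi2(aa, f)
        cache[key] = val
        return val

    return phi2(a, b) if a != b else 0.5


def _common_ancestor_diff_windows(ped: "Pedigree", sampled: list[str]):
    """Birth-difference windows implied by shared ancestors.

    For sampled a, b with a common ancestor at (g1, g2) meioses, the births
    must satisfy birth_a - birth_b in [g2*lo - g1*hi, g2*hi - g1*lo] for the
    parental-age window [lo, hi] (full siblings: +-(hi - lo)).  Yields
    (a, b, g1, g2) triples using minimal path lengths per shared ancestor.
    """
    dists = {}
    for iid in sampled:
        d: dict[str, int] = {iid: 0}
        stack = [(iid, 0)]
        while stack:
            x, k = stack.pop()
            for pid in ped.parents(x):
                if pid is None:
                    continue
                if pid not in d or k + 1 < d[pid]:
                    d[pid] = k + 1
                    stack.append((pid, k + 1))
        dists[iid] = d
    seen = set()
    for a, b in itertools.combinations(sampled, 2):
        for anc in set(dists[a]) & set(dists[b]):
            g1, g2 = dists[a][anc], dists[b][anc]
            if g1 == 0 or g2 == 0:
                continue  # ancestor-descendant pairs handled separately
            key = (a, b, g1, g2)
            if key not in seen:
                seen.add(key)
                yield key


def _diff_window_feasible(iv_a, iv_b, g1, g2, gap):
    if iv_a is None or iv_b is None:
        return True
    lo, hi = gap
    w_lo, w_hi = g2 * lo - g1 * hi, g2 * hi - g1 * lo
    d_lo, d_hi = iv_a[0] - iv_b[1], iv_a[1] - iv_b[0]
    return d_hi >= w_lo and d_lo <= w_hi


def _sampled_ancestor_gaps(ped: "Pedigree", sampled: list[str]):
    """(ancestor, descendant, min meiosis count) for sampled pairs joined by
    an ancestor path, possibly through latent individuals."""
    out = []
    for desc in sampled:
        dists: dict[str, int] = {}
        stack = [(desc, 0)]
        while stack:
            x, d = stack.pop()
            for pid in ped.parents(x):
                if pid is None:
                    continue
                if pid not in dists or d + 1 < dists[pid]:
                    dists[pid] = d + 1
                    stack.append((pid, d + 1))
        for anc, g in dists.items():
            if anc in sampled:
                out.append((anc, desc, g))
    return out


def canonical_form(ped: Pedigree, sampled_ids: list[str]) -> frozenset:
    """Canonical edge set with latent nodes renamed by structural signature.

    Latent nodes are relabeled by iteratively refined signatures built from
    their sex and the canonical names of their children; the result is
    invariant to the arbitrary creation order of latent nodes.
    """
    latent = [i.id for i in ped if not i.sampled]
    names = {i: i for i in ped.ids if i not in latent}
    sig = {l: (ped.members[l].sex,) for l in latent}
    for _ in range(len(latent) + 2):
        newsig = {}
        for l in latent:
            kids = sorted(
                names.get(c, "?" + str(sig.get(c, ""))) for c in ped.children(l)
            )
            pars = sorted(
                names.get(p, "?" + str(sig.get(p, "")))
                for p in ped.parents(l)
                if p is not None
            )
            newsig[l] = (ped.members[l].sex, tuple(kids), tuple(pars))
        sig = newsig
    ranked = sorted(latent, key=lambda l: (sig[l], l))
    for n, l in enumerate(ranked):
        names[l] = f"_L{n}{ped.members[l].sex}"
    edges = set()
    for ind in ped:
        for pid, role in ((ind.mother, "m"), (ind.father, "f")):
            if pid is not None:
                edges.add((names[ind.id], role, names[pid]))
    for ind in ped:
        edges.add((names[ind.id], "node", ind.sex))
    return frozenset(edges)


# ---------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------

@dataclass
class ScoredPedigree:
    pedigree: Pedigree
    score: float
    breakdown: dict[str, float] = field(default_factory=dict)
    vetoed: bool = False
    tied_with: list[int] = field(default_factory=list)


def _normal_gap_logprob(
    parent_iv: tuple[float, float],
    child_iv: tuple[float, float],
    gap: tuple[float, float] = (PARENT_AGE_MIN, PARENT_AGE_MAX),
) -> float:
    """log P(child_birth - parent_birth in gap window).

    95% intervals are read as Normal(mid, width/4); the difference is Normal.
    """
    from scipy.stats import norm

    mp, sp = 0.5 * (parent_iv[0] + parent_iv[1]), max((parent_iv[1] - parent_iv[0]) / 4.0, 1.0)
    mc, sc = 0.5 * (child_iv[0] + child_iv[1]), max((child_iv[1] - child_iv[0]) / 4.0, 1.0)
    mu, sd = mc - mp, math.hypot(sp, sc)
    p = norm.cdf((gap[1] - mu) / sd) - norm.cdf((gap[0] - mu) / sd)
    return math.log(max(p, 1e-300))


def score_candidates(
    candidates: list[Pedigree],
    evidence: EvidenceSet,
    degree_mismatch_penalty: float = 6.0,
    type_weight: float = 0.25,
    latent_penalty: float = 0.5,
    gap: tuple[float, float] = (PARENT_AGE_MIN, PARENT_AGE_MAX),
) -> list[ScoredPedigree]:
    """Rank candidate pedigrees by an additive log-score.

    Components: degree agreement (confidence-weighted), mt-lineage
    consistency (hard veto on a maternal-path mismatch), parent-child
    birth-interval gap probabilities, sibling/parent-offspring HMM margins,
    and a mild complexity penalty per latent individual.  Ties (scores within
    1e-9) are cross-referenced, never silently broken.
    """
    if not candidates:
        raise ValueError("score_candidates requires a nonempty candidate list")
    sampled = list(evidence.individuals)
    birth_ivs = {i: _birth_interval(evidence, i) for i in sampled}
    scored: list[ScoredPedigree] = []
    for ped in candidates:
        parts = {"degree": 0.0, "mt": 0.0, "gap": 0.0, "type": 0.0, "complexity": 0.0}
        vetoed = False
        for a, b in itertools.combinations(sampled, 2):
            pe = evidence.pair(a, b)
            d = ped.degree(a, b)
            if pe.degree not in ("undetermined",):
                lo, hi = _phi_band(pe.degree)
                phi = ped.kinship(a, b)
                if not (lo <= phi <= hi):
                    want = pe.degree
                    got = DEGREE_LABELS.get(d, "unrelated") if d is not None else "unrelated"
                    dist = abs(
                        "identical 1st 2nd 3rd unrelated".split().index(want)
                        - "identical 1st 2nd 3rd unrelated".split().index(got)
                    )
                    parts["degree"] -= degree_mismatch_penalty * pe.confidence * dist
            if pe.first_degree_type and d == 1:
                mo_a, fa_a = ped.parents(a)
                mo_b, fa_b = ped.parents(b)
                is_po = a in (mo_b, fa_b) or b in (mo_a, fa_a)
                rel = "parent-offspring" if is_po else "sibling"
                sgn = 1.0 if rel == pe.first_degree_type else -1.0
                parts["type"] += sgn * type_weight * min(abs(pe.type_margin), 20.0)
        # mt-lineage hard veto
        roots: dict[str, set] = {}
        for iid in sampled:
            lab = evidence.individuals[iid].mt_lineage
            if lab is None:
                continue
            roots.setdefault(ped.matriline_root(iid), set()).add(lab)
        if any(len(v) > 1 for v in roots.values()):
            vetoed = True
            parts["mt"] = -math.inf
        # birth-gap probabilities on ancestor paths between sampled pairs
        for anc, desc, g in _sampled_ancestor_gaps(ped, sampled):
            piv, civ = birth_ivs.get(anc), birth_ivs.get(desc)
            if piv is None or civ is None:
                continue
            parts["gap"] += _normal_gap_logprob(
                piv, civ, (g * gap[0], g * gap[1])
            )
            if not _gap_feasible(piv, civ, (g * gap[0], g * gap[1])):
                vetoed = True
                parts["gap"] = -math.inf
        for a, b, g1, g2 in _common_ancestor_diff_windows(ped, sampled):
            if not _diff_window_feasible(
                birth_ivs.get(a), birth_ivs.get(b), g1, g2, gap
            ):
                vetoed = True
                parts["gap"] = -math.inf
        n_latent = sum(1 for i in ped if not i.sampled)
        parts["complexity"] = -latent_penalty * n_latent
        total = sum(parts.values())
        scored.append(ScoredPedigree(ped, total, parts, vetoed))
    scored.sort(key=lambda s: -s.score)
    for i, s in enumerate(scored):
        s.tied_with = [
            j
            for j, t in enumerate(scored)
            if j != i and abs(t.score - s.score) < 1e-9
        ]
    return scored
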