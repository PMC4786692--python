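"""Linker reach, engagement classification, species enumeration and matching."""

import itertools

import networkx as nx
import pytest

import dabengage as de
from dabengage.geometry import TerminalDistanceReport
from dabengage.topology import EnumerationOverflowError, TopologyError


# --------------------------------------------------------------------------
# brute-force enumeration oracle: exhaustively assign epitope slots to site
# slots, keep valid connected assemblies, canonicalise by minimising the
# type-labelled edge list over all binder/antigen index permutations.
# --------------------------------------------------------------------------

def _oracle_canonical(edges_types, n_b, n_a):
    best = None
    for pb in itertools.permutations(range(n_b)):
        for pa in itertools.permutations(range(n_a)):
            relabeled = tuple(sorted((pb[b], t, pa[a]) for (b, t, a) in edges_types))
            if best is None or relabeled < best:
                best = relabeled
    return (n_b, n_a, best)


def brute_force_species(architecture, antigen, max_b, max_a, rules=None):
    rules = rules if rules is not None else architecture.rules
    site_names = [s.name for s in architecture.sites]
    domains = {s.name: s.domain for s in architecture.sites}
    canon = set()
    for n_b in range(1, max_b + 1):
        for n_a in range(1, max_a + 1):
            epitope_slots = [(a, e) for a in range(n_a) for e in range(antigen.epitopes_per_unit)]
            site_slots = [(b, s) for b in range(n_b) for s in site_names]

            def valid(assignment):
                # assignment: epitope slot index -> site slot or None
                edges = [
                    (b, s, a, e)
                    for (a, e), slot in zip(epitope_slots, assignment)
                    if slot is not None
                    for (b, s) in [slot]
                ]
                if not edges:
                    return None
                used_binders = {b for b, _, _, _ in edges}
                used_antigens = {a for _, _, a, _ in edges}
                if used_binders != set(range(n_b)) or used_antigens != set(range(n_a)):
                    return None
                # per-antigen rule check
                by_antigen = {}
                for b, s, a, e in edges:
                    by_antigen.setdefault(a, []).append((b, s))
                for a, bound in by_antigen.items():
                    if len(bound) == 2:
                        (b1, s1), (b2, s2) = bound
                        if b1 == b2:
                            if not rules.clamp_allowed(s1, s2):
                                return None
                        elif not rules.intermolecular_sharing:
                            return None
                g = nx.Graph()
                g.add_nodes_from(("b", b) for b in range(n_b))
                g.add_nodes_from(("a", a) for a in range(n_a))
                g.add_edges_from((("b", b), ("a", a)) for b, _, a, _ in edges)
                if not nx.is_connected(g):
                    return None
                return edges

            options = [None] + site_slots
            for assignment in itertools.product(options, repeat=len(epitope_slots)):
                slots = [x for x in assignment if x is not None]
                if len(set(slots)) != len(slots):
                    continue  # a site slot bound twice
                edges = valid(assignment)
                if edges is None:
                    continue
                types = [(b, domains[s], a) for b, s, a, _ in edges]
                canon.add(_oracle_canonical(types, n_b, n_a))
    return canon


def _catalog_canon(catalog):
    domains = {s.name: s.domain for s in catalog.architecture.sites}
    out = set()
    for sp in catalog.species:
        types = [(b, domains[s], a) for (b, s, a, _e) in sp.edges]
        out.add(_oracle_canonical(types, sp.n_binders, sp.n_antigens))
    return out


# --------------------------------------------------------------------------
# linker reach and feasibility
# --------------------------------------------------------------------------

class TestLinkerSpan:
    @pytest.mark.parametrize(
        "n,contour,expected",
        [(0, 3.5, 0.0), (10, 3.5, 35.0), (15, 3.8, 57.0), (15, 3.5, 52.5)],
    )
    def test_contour_length(self, n, contour, expected):
        assert de.max_linker_span(de.LinkerSpec(n, contour)) == pytest.approx(expected)

    def test_invalid_specs_rejected(self):
        with pytest.raises(TopologyError):
            de.LinkerSpec(-1)
        with pytest.raises(TopologyError):
            de.LinkerSpec(10, contour_per_residue=2.0)


class TestCoengagementFeasibility:
    def test_zero_required_span_is_trivially_feasible(self):
        v = de.coengagement_feasibility(0.0, [de.LinkerSpec(15)])
        assert v.verdict == "feasible" and v.extension_fraction == 0.0

    def test_end_on_vh_pair_cannot_easily_span_81(self, dual_dab):
        vh = dual_dab.site("vh1").linker
        v = de.coengagement_feasibility(81.0, [vh, vh], dual_dab.anchor_span("vh_vh"))
        assert v.verdict in ("marginal", "infeasible")
        assert v.extension_fraction > de.topology.FEASIBLE_MAX_EXTENSION

    @pytest.mark.parametrize("distance,pair", [(70.0, "vk_vk"), (77.0, "cross")])
    def test_c_terminal_and_cross_pairs_easily_span(self, dual_dab, distance, pair):
        linkers = {
            "vk_vk": [dual_dab.site("vk1").linker, dual_dab.site("vk2").linker],
            "cross": [dual_dab.site("vh1").linker, dual_dab.site("vk1").linker],
        }[pair]
        v = de.coengagement_feasibility(distance, linkers, dual_dab.anchor_span(pair))
        assert v.verdict == "feasible"

    def test_extension_fraction_identity(self):
        v = de.coengagement_feasibility(50.0, [de.LinkerSpec(10)], 15.0)
        assert v.available_span == pytest.approx(50.0)
        assert v.extension_fraction == pytest.approx(v.required_span / v.available_span)

    def test_monotone_in_linker_length(self):
        # lengthening any linker never flips feasible -> infeasible
        order = {"feasible": 0, "marginal": 1, "infeasible": 2}
        prev = None
        for n in range(0, 40, 2):
            v = de.coengagement_feasibility(60.0, [de.LinkerSpec(n), de.LinkerSpec(5)])
            if prev is not None:
                assert order[v.verdict] <= order[prev]
            prev = v.verdict

    def test_negative_span_rejected(self):
        with pytest.raises(TopologyError):
            de.coengagement_feasibility(-1.0, [de.LinkerSpec(5)])


class TestClassifyEngagementMode:
    def test_measured_distances_classify_side_on(self, dual_dab):
        rep = TerminalDistanceReport(d_vh_vh=81.0, d_vk_vk=70.0, d_cross=77.0)
        cls = de.classify_engagement_mode(rep, dual_dab)
        assert cls.mode == "side-on"
        assert not cls.verdicts["vh_vh"].feasible
        assert cls.verdicts["cross"].feasible and cls.verdicts["vk_vk"].feasible

    def test_zero_distances_classify_end_on(self, dual_dab):
        cls = de.classify_engagement_mode(
            TerminalDistanceReport(d_vh_vh=0.0, d_vk_vk=0.0, d_cross=0.0), dual_dab
        )
        assert cls.mode == "end-on"

    def test_unreachable_distances_classify_none(self, dual_dab):
        big = 10.0 * (2 * de.max_linker_span(dual_dab.site("vh1").linker) + 20.0)
        cls = de.classify_engagement_mode(
            TerminalDistanceReport(d_vh_vh=big, d_vk_vk=big, d_cross=big), dual_dab
        )
        assert cls.mode == "none"
        assert all(v.verdict == "infeasible" for v in cls.verdicts.values())

    def test_missing_distances_flagged(self, dual_dab):
        cls = de.classify_engagement_mode(TerminalDistanceReport(d_vh_vh=81.0), dual_dab)
        assert "cross" in cls.missing and "vk_vk" in cls.missing
        assert cls.mode == "indeterminate"


# --------------------------------------------------------------------------
# species enumeration
# --------------------------------------------------------------------------

class TestEnumeration:
    def test_monovalent_binder_matches_hand_enumeration(self, vegf):
        cat = de.enumerate_species(de.monovalent_architecture(), vegf, 2, 2)
        assert cat.labels() == {"1:1", "2:1"}

    @pytest.mark.parametrize(
        "arch_factory,limits",
        [
            (de.monovalent_architecture, (3, 3)),
            (de.igg_architecture, (3, 3)),
            (de.trap_architecture, (3, 3)),
            (de.dual_dab_architecture, (2, 2)),
        ],
    )
    def test_equals_brute_force_enumeration(self, vegf, arch_factory, limits):
        arch = arch_factory()
        cat = de.enumerate_species(arch, vegf, *limits)
        assert _catalog_canon(cat) == brute_force_species(arch, vegf, *limits)

    def test_no_duplicate_isomorphic_species(self, vegf, dual_dab):
        cat = de.enumerate_species(dual_dab, vegf, 3, 3)
        canon = _catalog_canon(cat)
        assert len(canon) == len(cat.species)

    def test_dual_dab_rules_close_only_at_1to1_and_1to2(self, vegf, dual_dab):
        cat = de.enumerate_species(dual_dab, vegf, 3, 3)
        assert cat.closed_labels() == {"1:1", "1:2"}
        # no sharing -> no species with more than one binder
        assert all(sp.n_binders == 1 for sp in cat.species)
        assert all(sp.n_antigens <= 3 for sp in cat.species)

    def test_igg_rules_grow_rings_and_chains(self, vegf):
        cat = de.enumerate_species(de.igg_architecture(), vegf, 4, 4)
        closed = cat.closed_labels()
        assert "2:2" in closed  # the ring the conventional IgG predominates as
        assert {"3:3", "4:4"} <= closed  # larger rings keep appearing up to the caps
        assert "1:1" not in closed  # a bivalent binder cannot clamp one antigen

    def test_mass_follows_composition(self, vegf, dual_dab):
        cat = de.enumerate_species(dual_dab, vegf, 2, 2)
        for sp in cat.species:
            assert sp.mass_kda == pytest.approx(
                de.species_mass(sp.n_binders, sp.n_antigens, dual_dab, vegf)
            )

    def test_enumeration_overflow_guard(self, vegf):
        with pytest.raises(EnumerationOverflowError):
            de.enumerate_species(de.igg_architecture(), vegf, 6, 6, max_species=5)

    def test_limits_validated(self, vegf, dual_dab):
        with pytest.raises(TopologyError):
            de.enumerate_species(dual_dab, vegf, 0, 1)


class TestSpeciesMass:
    @pytest.mark.parametrize(
        "nb,na,bm,am,expected",
        [(1, 2, 109.0, 48.0, 205.0), (2, 2, 148.0, 48.0, 392.0), (0, 1, 109.0, 48.0, 48.0)],
    )
    def test_additive_mass(self, nb, na, bm, am, expected):
        arch = de.dual_dab_architecture(molecule_mass_kda=bm) if bm != 148.0 else de.igg_architecture(bm)
        assert de.species_mass(nb, na, arch, de.vegf_antigen(am)) == pytest.approx(expected)

    def test_negative_counts_rejected(self, vegf, dual_dab):
        with pytest.raises(TopologyError):
            de.species_mass(-1, 0, dual_dab, vegf)


class TestMatchSpecies:
    def test_observed_interval_selects_1to2_dual_dab_species(self, vegf, dual_dab):
        cat = de.enumerate_species(dual_dab, vegf, 4, 4)
        ranked = de.match_species(cat, (183.0, 201.0))
        assert ranked, "no species matched the observed interval"
        assert ranked[0][0].label == "1:2"
        assert ranked[0][0].mass_kda == pytest.approx(205.0)

    def test_observed_397_selects_2to2_igg_species(self, vegf):
        cat = de.enumerate_species(de.igg_architecture(), vegf, 4, 4)
        ranked = de.match_species(cat, 397.0)
        assert ranked[0][0].label == "2:2"
        assert ranked[0][0].mass_kda == pytest.approx(392.0)

    def test_exact_mass_ranks_first_with_zero_error(self, vegf, dual_dab):
        cat = de.enumerate_species(dual_dab, vegf, 2, 2)
        target = cat.species[0].mass_kda
        ranked = de.match_species(cat, target)
        assert ranked[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_tolerance_rejected(self, vegf, dual_dab):
        cat = de.enumerate_species(dual_dab, vegf, 2, 2)
        with pytest.raises(TopologyError):
            de.match_species(cat, 100.0, rel_tol=0.0)
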