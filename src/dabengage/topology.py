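"""Linker reach, engagement-mode classification, and complex-species enumeration.

A dual-dAb molecule is an Fc homodimer whose each monomer carries a V_H
domain antibody fused through a peptide linker at the Fc N terminus and a V_κ
domain antibody through a linker at the Fc C terminus — four antigen-binding
sites per molecule, two per "half". The antigen (a VEGF homodimer) presents
two equivalent epitopes. Whether two sites of one molecule can clamp both
epitopes of a single antigen depends on whether their linkers can span the
measured inter-terminal distance:

* end-on clamp: the two V_H sites reach over the top of the molecule — both
  N-terminal linkers must cover ~81 Å from a shared hinge anchor;
* side-on clamp: one V_H and the same half's V_κ wrap around one antigen —
  the cross distance (~77 Å) is covered by one N-terminal plus one C-terminal
  linker *and* the span of the Fc between their attachment points.

Feasible clamps are expressed as assembly rules under which all connected
binder:antigen species are enumerated (up to isomorphism) and their masses
compared with SEC-MALLS observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import networkx as nx

from .geometry import TerminalDistanceReport

__all__ = [
    "LinkerSpec",
    "Site",
    "AssemblyRules",
    "BinderArchitecture",
    "AntigenModel",
    "CoEngagementVerdict",
    "EngagementClassification",
    "SpeciesGraph",
    "SpeciesCatalog",
    "TopologyError",
    "EnumerationOverflowError",
    "max_linker_span",
    "coengagement_feasibility",
    "classify_engagement_mode",
    "enumerate_species",
    "species_mass",
    "match_species",
    "dual_dab_architecture",
    "igg_architecture",
    "trap_architecture",
    "monovalent_architecture",
    "vegf_antigen",
]


class TopologyError(ValueError):
    """Invalid linker/architecture/antigen parameterization."""


class EnumerationOverflowError(RuntimeError):
    """Species enumeration exceeded its configured cap."""


# --------------------------------------------------------------------------
# linker reach
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkerSpec:
    """A peptide linker modelled by its contour length.

    ``contour_per_residue`` is the extended-chain rise per residue
    (literature range ≈3.4–3.8 Å; 3.5 Å default). ``anchor_allowance`` is
    slack for the separation of the linker attachment points on the Fc and is
    *not* part of :func:`max_linker_span`; it enters feasibility checks as the
    shared anchor span.
    """

    n_residues: int
    contour_per_residue: float = 3.5
    anchor_allowance: float = 10.0

    def __post_init__(self) -> None:
        if self.n_residues < 0:
            raise TopologyError("linker length must be >= 0 residues")
        if not 3.0 <= self.contour_per_residue <= 3.8:
            raise TopologyError("contour per residue must lie in [3.0, 3.8] Å")
        if self.anchor_allowance < 0:
            raise TopologyError("anchor allowance must be >= 0")


def max_linker_span(linker: LinkerSpec) -> float:
    """Fully-extended contour length of a linker in Å (no anchor term)."""
    return linker.n_residues * linker.contour_per_residue


@dataclass(frozen=True)
class Site:
    """One antigen-binding site of a binder molecule."""

    name: str  # unique within the molecule, e.g. "vh1"
    domain: str  # "vh", "vk", "fab", "trap"
    half: int  # monomer index within the homodimer (0-based)
    linker: LinkerSpec
    attachment: str = "n_term"  # terminus of the Fc the linker attaches to


@dataclass(frozen=True)
class AssemblyRules:
    """Which multi-site engagements of a single antigen are allowed.

    ``allowed_clamps`` lists unordered pairs of site *names* of one molecule
    that may occupy both epitopes of the same antigen (an intramolecular
    clamp). ``intermolecular_sharing`` permits sites of two different binder
    molecules to occupy the two epitopes of one antigen — this is what lets
    conventional IgGs polymerise into chains and rings.
    """

    allowed_clamps: frozenset = frozenset()
    intermolecular_sharing: bool = True

    def clamp_allowed(self, site_a: str, site_b: str) -> bool:
        return frozenset((site_a, site_b)) in self.allowed_clamps


@dataclass
class BinderArchitecture:
    name: str
    sites: list[Site]
    copies_per_molecule: int  # monomers per molecule (2 for an Fc homodimer)
    molecule_mass_kda: float
    rules: AssemblyRules = field(default_factory=AssemblyRules)
    #: anchor span in Å between the two linker attachment points, per pair kind
    anchor_spans: dict = field(default_factory=dict)
    intramolecular_clamp_allowed: bool = True

    def __post_init__(self) -> None:
        if self.molecule_mass_kda <= 0:
            raise TopologyError("molecule mass must be positive")
        if not self.sites:
            raise TopologyError("architecture needs at least one site")
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise TopologyError(f"duplicate site names: {names}")

    def site(self, name: str) -> Site:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(name)

    def anchor_span(self, pair_kind: str) -> float:
        return float(self.anchor_spans.get(pair_kind, 0.0))


@dataclass
class AntigenModel:
    name: str
    epitopes_per_unit: int
    unit_mass_kda: float

    def __post_init__(self) -> None:
        if self.epitopes_per_unit < 1:
            raise TopologyError("antigen needs at least one epitope")
        if self.unit_mass_kda <= 0:
            raise TopologyError("antigen unit mass must be positive")


# --------------------------------------------------------------------------
# co-engagement feasibility and engagement-mode classification
# --------------------------------------------------------------------------

#: extension-fraction cutoffs: a clamp requiring less than 75% of the fully
#: extended reach "easily spans" the distance; between 75% and 95% it requires
#: an extremely extended (unlikely) conformation; above 95% it is infeasible.
FEASIBLE_MAX_EXTENSION = 0.75
MARGINAL_MAX_EXTENSION = 0.95


@dataclass
class CoEngagementVerdict:
    pair: tuple[str, str]
    required_span: float  # Å
    available_span: float  # Å
    verdict: str  # "feasible" | "marginal" | "infeasible"
    extension_fraction: float

    @property
    def feasible(self) -> bool:
        return self.verdict == "feasible"


def coengagement_feasibility(
    required_span: float,
    linkers: Sequence[LinkerSpec],
    shared_anchor_span: float = 0.0,
    *,
    pair: tuple[str, str] = ("a", "b"),
    feasible_max: float = FEASIBLE_MAX_EXTENSION,
    marginal_max: float = MARGINAL_MAX_EXTENSION,
) -> CoEngagementVerdict:
    """Can a set of linkers bridge ``required_span`` from a shared anchor?

    The available span is the sum of the fully extended linker contour
    lengths plus the separation of their anchor points; the verdict compares
    the required span against that reach through the extension fraction.
    """
    if required_span < 0 or shared_anchor_span < 0:
        raise TopologyError("spans must be non-negative")
    available = sum(max_linker_span(l) for l in linkers) + shared_anchor_span
    if required_span == 0:
        fraction = 0.0
    elif available == 0:
        fraction = float("inf")
    else:
        fraction = required_span / available
    if fraction <= feasible_max:
        verdict = "feasible"
    elif fraction <= marginal_max:
        verdict = "marginal"
    else:
        verdict = "infeasible"
    return CoEngagementVerdict(
        pair=tuple(pair),
        required_span=float(required_span),
        available_span=float(available),
        verdict=verdict,
        extension_fraction=float(fraction),
    )


@dataclass
class EngagementClassification:
    verdicts: dict  # {"vh_vh": CoEngagementVerdict | None, "vk_vk": ..., "cross": ...}
    mode: str  # "side-on" | "end-on" | "none" | "indeterminate"
    missing: list[str] = field(default_factory=list)


def classify_engagement_mode(
    report: TerminalDistanceReport, architecture: BinderArchitecture
) -> EngagementClassification:
    """Classify the likely engagement mode from inter-terminal distances.

    * ``end-on``: both like-domain clamps (V_H–V_H across the top *and*
      V_κ–V_κ across the bottom) are feasible.
    * ``side-on``: the V_H–V_H clamp is not feasible while the cross
      (V_H + same-half V_κ) clamp is — each half of the molecule then wraps
      around its own antigen, giving two antigens per molecule.
    * ``none``: no clamp feasible.
    """
    vh_sites = [s for s in architecture.sites if s.domain == "vh"]
    vk_sites = [s for s in architecture.sites if s.domain == "vk"]
    if not vh_sites or not vk_sites:
        raise TopologyError("engagement classification needs vh and vk sites")
    vh, vk = vh_sites[0], vk_sites[0]

    specs = {
        "vh_vh": (report.d_vh_vh, [vh.linker, vh.linker]),
        "vk_vk": (report.d_vk_vk, [vk.linker, vk.linker]),
        "cross": (report.d_cross, [vh.linker, vk.linker]),
    }
    verdicts: dict[str, Optional[CoEngagementVerdict]] = {}
    missing: list[str] = []
    for key, (distance, linkers) in specs.items():
        if distance is None:
            verdicts[key] = None
            missing.append(key)
            continue
        verdicts[key] = coengagement_feasibility(
            distance, linkers, architecture.anchor_span(key), pair=(key, key)
        )

    def ok(key: str) -> Optional[bool]:
        v = verdicts[key]
        return None if v is None else v.feasible

    if ok("vh_vh") and ok("vk_vk"):
        mode = "end-on"
    elif ok("cross") and ok("vh_vh") is False:
        mode = "side-on"
    elif missing:
        mode = "indeterminate"
    else:
        mode = "none"
    return EngagementClassification(verdicts=verdicts, mode=mode, missing=missing)


# --------------------------------------------------------------------------
# species enumeration
# --------------------------------------------------------------------------

Edge = tuple[int, str, int, int]  # (binder index, site name, antigen index, epitope index)


@dataclass
class SpeciesGraph:
    n_binders: int
    n_antigens: int
    edges: list  # list[Edge]
    mass_kda: float
    label: str  # "n_binders:n_antigens"

    @property
    def is_closed(self) -> bool:
        """True when every epitope of every antigen in the species is bound."""
        epitopes_bound = {(a, e) for (_, _, a, e) in self.edges}
        n_epitopes = len({(a, e) for (a, e) in epitopes_bound})
        # epitopes per antigen is implied by the edges' epitope index range
        return all(
            (a, e) in epitopes_bound
            for a in range(self.n_antigens)
            for e in range(self._epitopes_per_unit)
        )

    _epitopes_per_unit: int = 2

    def to_multigraph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for b in range(self.n_binders):
            g.add_node(("b", b), kind="binder")
        for a in range(self.n_antigens):
            g.add_node(("a", a), kind="antigen")
        for (b, site, a, _e) in self.edges:
            g.add_edge(("b", b), ("a", a), site_type=site.rstrip("0123456789"))
        return g


@dataclass
class SpeciesCatalog:
    species: list  # list[SpeciesGraph]
    max_binders: int
    max_antigens: int
    architecture: BinderArchitecture = None
    antigen: AntigenModel = None

    def closed_labels(self) -> set:
        return {s.label for s in self.species if s.is_closed}

    def labels(self) -> set:
        return {s.label for s in self.species}


def species_mass(
    n_binders: int,
    n_antigens: int,
    architecture: BinderArchitecture,
    antigen: AntigenModel,
) -> float:
    """Additive species mass in kDa: n_b·M_binder + n_a·M_antigen."""
    if n_binders < 0 or n_antigens < 0:
        raise TopologyError("counts must be non-negative")
    return n_binders * architecture.molecule_mass_kda + n_antigens * antigen.unit_mass_kda


def _edge_addition_allowed(
    edges: frozenset, new_edge: Edge, rules: AssemblyRules
) -> bool:
    b, site, a, e = new_edge
    for (b2, site2, a2, e2) in edges:
        if a2 == a and e2 == e:
            return False  # epitope occupied
        if b2 == b and site2 == site:
            return False  # site occupied
        if a2 == a:  # the antigen's other epitope is already bound
            if b2 == b:
                if not rules.clamp_allowed(site, site2):
                    return False
            elif not rules.intermolecular_sharing:
                return False
    return True


def _canonical_key(sp: SpeciesGraph) -> tuple:
    g = sp.to_multigraph()
    site_types = tuple(sorted(d["site_type"] for _, _, d in g.edges(data=True)))
    wl = nx.weisfeiler_lehman_graph_hash(nx.Graph(g), node_attr="kind", iterations=3)
    return (sp.n_binders, sp.n_antigens, site_types, wl)


def _isomorphic(sp1: SpeciesGraph, sp2: SpeciesGraph) -> bool:
    return nx.is_isomorphic(
        sp1.to_multigraph(),
        sp2.to_multigraph(),
        node_match=lambda a, b: a["kind"] == b["kind"],
        edge_match=lambda a, b: sorted(d["site_type"] for d in a.values())
        == sorted(d["site_type"] for d in b.values()),
    )


def enumerate_species(
    architecture: BinderArchitecture,
    antigen: AntigenModel,
    max_binders: int,
    max_antigens: int,
    rules: Optional[AssemblyRules] = None,
    *,
    include_free: bool = False,
    max_species: int = 10_000,
) -> SpeciesCatalog:
    """Enumerate all connected, non-isomorphic binder:antigen complex species.

    Species are grown edge-by-edge from a single bound pair: at each step a
    new antigen is attached to a free site, a new binder is attached to a free
    epitope, or a free site is joined to a free epitope within the species
    (the clamp / ring-closure move). Every addition must respect the assembly
    rules: one bond per site, one per epitope, intramolecular clamps only for
    allowed site pairs, and intermolecular sharing of one antigen only when
    the rules permit it. Isomorphic duplicates (same connectivity with sites
    distinguished by domain type only) are removed.

    ``include_free`` appends the unbound binder ("1:0") and unbound antigen
    ("0:1") to the catalog — useful when matching chromatogram peaks, where
    free components elute alongside the complexes.
    """
    if max_binders < 1 or max_antigens < 1:
        raise TopologyError("enumeration limits must be >= 1")
    rules = rules if rules is not None else architecture.rules
    site_names = [s.name for s in architecture.sites]
    epitopes = range(antigen.epitopes_per_unit)

    def make_species(n_b: int, n_a: int, edges: frozenset) -> SpeciesGraph:
        sp = SpeciesGraph(
            n_binders=n_b,
            n_antigens=n_a,
            edges=sorted(edges),
            mass_kda=species_mass(n_b, n_a, architecture, antigen),
            label=f"{n_b}:{n_a}",
        )
        sp._epitopes_per_unit = antigen.epitopes_per_unit
        return sp

    seen: dict[tuple, list[SpeciesGraph]] = {}
    results: list[SpeciesGraph] = []
    frontier: list[tuple[int, int, frozenset]] = []

    def register(n_b: int, n_a: int, edges: frozenset) -> None:
        sp = make_species(n_b, n_a, edges)
        key = _canonical_key(sp)
        bucket = seen.setdefault(key, [])
        if any(_isomorphic(sp, other) for other in bucket):
            return
        bucket.append(sp)
        results.append(sp)
        frontier.append((n_b, n_a, edges))
        if len(results) > max_species:
            raise EnumerationOverflowError(
                f"species enumeration exceeded cap of {max_species}; "
                "lower the limits or raise max_species"
            )

    # seeds: one binder, one antigen, one bond per distinct site domain
    seeded_domains = set()
    for name in site_names:
        domain = architecture.site(name).domain
        if domain in seeded_domains:
            continue
        seeded_domains.add(domain)
        register(1, 1, frozenset({(0, name, 0, 0)}))

    while frontier:
        n_b, n_a, edges = frontier.pop()
        free_sites = [
            (b, name)
            for b in range(n_b)
            for name in site_names
            if not any(e[0] == b and e[1] == name for e in edges)
        ]
        free_epitopes = [
            (a, e)
            for a in range(n_a)
            for e in epitopes
            if not any(ed[2] == a and ed[3] == e for ed in edges)
        ]
        # move 1: attach a new antigen to a free site
        if n_a < max_antigens:
            for (b, name) in free_sites:
                register(n_b, n_a + 1, edges | {(b, name, n_a, 0)})
        # move 2: attach a new binder to a free epitope
        if n_b < max_binders:
            for (a, e) in free_epitopes:
                for name in site_names:
                    new_edge = (n_b, name, a, e)
                    if _edge_addition_allowed(edges, new_edge, rules):
                        register(n_b + 1, n_a, edges | {new_edge})
        # move 3: close a bond inside the species (clamp or ring closure)
        for (b, name) in free_sites:
            for (a, e) in free_epitopes:
                new_edge = (b, name, a, e)
                if _edge_addition_allowed(edges, new_edge, rules):
                    register(n_b, n_a, edges | {new_edge})

    if include_free:
        for n_b, n_a in ((1, 0), (0, 1)):
            results.append(make_species(n_b, n_a, frozenset()))
    results.sort(key=lambda s: (s.n_binders, s.n_antigens, s.mass_kda, s.label, s.edges))
    return SpeciesCatalog(
        species=results,
        max_binders=max_binders,
        max_antigens=max_antigens,
        architecture=architecture,
        antigen=antigen,
    )


def match_species(
    catalog: SpeciesCatalog,
    observed_mass: Union[float, tuple],
    rel_tol: float = 0.15,
) -> list[tuple[SpeciesGraph, float]]:
    """Rank catalog species against an observed mass (kDa) or mass interval.

    A species matches a scalar observation when ``|pred − obs|/obs ≤ rel_tol``
    and an interval when its ±rel_tol band overlaps the interval; matches are
    ranked by relative error against the observation (interval midpoint).
    SEC-MALLS mass accuracy for protein conjugates is conventionally quoted at
    ±10–15%, hence the 0.15 default.
    """
    if rel_tol <= 0:
        raise TopologyError("relative tolerance must be positive")
    if not catalog.species:
        raise TopologyError("catalog is empty")
    if isinstance(observed_mass, (tuple, list)):
        lo, hi = float(observed_mass[0]), float(observed_mass[1])
        if lo <= 0 or hi < lo:
            raise TopologyError("invalid mass interval")
        centre = 0.5 * (lo + hi)

        def matches(pred: float) -> bool:
            return pred * (1 - rel_tol) <= hi and pred * (1 + rel_tol) >= lo

    else:
        obs = float(observed_mass)
        if obs <= 0:
            raise TopologyError("observed mass must be positive")
        lo = hi = centre = obs

        def matches(pred: float) -> bool:
            return abs(pred - obs) / obs <= rel_tol

    ranked = [
        (sp, abs(sp.mass_kda - centre) / centre)
        for sp in catalog.species
        if matches(sp.mass_kda)
    ]
    ranked.sort(key=lambda t: t[1])
    return ranked


# --------------------------------------------------------------------------
# reference architectures
# --------------------------------------------------------------------------

def dual_dab_architecture(
    vh_linker: LinkerSpec = LinkerSpec(15),
    vk_linker: LinkerSpec = LinkerSpec(15),
    molecule_mass_kda: float = 109.0,
    *,
    allow_vk_pair_clamp: bool = True,
    intermolecular_sharing: bool = False,
) -> BinderArchitecture:
    """The dual-dAb layout: per monomer V_H·dAb → linker → Fc → linker → V_κ·dAb.

    Defaults encode the side-on conclusion's assembly rules: each half's
    V_H + V_κ pair may clamp one antigen; the V_κ–V_κ clamp across the bottom
    of the molecule is geometrically possible and allowed; the V_H–V_H end-on
    clamp is not. Sharing one antigen between two molecules is off by default
    (the corresponding ~370 kDa species is not observed). The N-terminal
    linkers emanate from the adjacent hinge region (no anchor span); the
    C-terminal attachment points at the base of the Fc are ~10 Å apart, which
    also sets the cross-pair anchor.
    """
    sites = [
        Site("vh1", "vh", 0, vh_linker, "n_term"),
        Site("vk1", "vk", 0, vk_linker, "c_term"),
        Site("vh2", "vh", 1, vh_linker, "n_term"),
        Site("vk2", "vk", 1, vk_linker, "c_term"),
    ]
    clamps = {frozenset({"vh1", "vk1"}), frozenset({"vh2", "vk2"})}
    if allow_vk_pair_clamp:
        clamps.add(frozenset({"vk1", "vk2"}))
    return BinderArchitecture(
        name="dual-dAb",
        sites=sites,
        copies_per_molecule=2,
        molecule_mass_kda=molecule_mass_kda,
        rules=AssemblyRules(
            allowed_clamps=frozenset(clamps),
            intermolecular_sharing=intermolecular_sharing,
        ),
        anchor_spans={
            "vh_vh": 0.0,
            "vk_vk": vk_linker.anchor_allowance,
            "cross": vk_linker.anchor_allowance,
        },
    )


def igg_architecture(molecule_mass_kda: float = 148.0) -> BinderArchitecture:
    """A conventional IgG: two equivalent Fab sites, no intramolecular clamp.

    The Fab arms of an IgG cannot wrap both epitopes of one small antigen
    homodimer, but two different IgG molecules can share one antigen — the
    rule set that produces (1:1)_n rings and open chains.
    """
    fab = LinkerSpec(0, anchor_allowance=0.0)
    sites = [Site("fab1", "fab", 0, fab), Site("fab2", "fab", 1, fab)]
    return BinderArchitecture(
        name="IgG",
        sites=sites,
        copies_per_molecule=2,
        molecule_mass_kda=molecule_mass_kda,
        rules=AssemblyRules(allowed_clamps=frozenset(), intermolecular_sharing=True),
        intramolecular_clamp_allowed=False,
    )


def trap_architecture(molecule_mass_kda: float = 115.0) -> BinderArchitecture:
    """A receptor-trap inhibitor engaging one antigen dimer per molecule (1:1)."""
    sites = [Site("trap1", "trap", 0, LinkerSpec(0, anchor_allowance=0.0))]
    return BinderArchitecture(
        name="trap",
        sites=sites,
        copies_per_molecule=2,
        molecule_mass_kda=molecule_mass_kda,
        rules=AssemblyRules(allowed_clamps=frozenset(), intermolecular_sharing=False),
        intramolecular_clamp_allowed=False,
    )


def monovalent_architecture(molecule_mass_kda: float = 13.0) -> BinderArchitecture:
    """A single-site binder (an isolated dAb); antigens may be shared."""
    sites = [Site("s1", "site", 0, LinkerSpec(0, anchor_allowance=0.0))]
    return BinderArchitecture(
        name="monovalent",
        sites=sites,
        copies_per_molecule=1,
        molecule_mass_kda=molecule_mass_kda,
        rules=AssemblyRules(allowed_clamps=frozenset(), intermolecular_sharing=True),
        intramolecular_clamp_allowed=False,
    )


def vegf_antigen(unit_mass_kda: float = 48.0) -> AntigenModel:
    """The VEGF homodimer: one antigen unit presenting two equivalent epitopes."""
    return AntigenModel(name="VEGF dimer", epitopes_per_unit=2, unit_mass_kda=unit_mass_kda)
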