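"""Synthetic inputs with known ground truth: toy complexes, mixing series, kinetics.

Nothing downstream needs real deposited coordinates to be exercised: the
geometry code consumes Cα positions, the SEC-MALLS code consumes detector
traces, and the kinetics code consumes sensorgrams. This module builds all
three from explicit ground truth so every recovery test can compare against a
manifest rather than the simulated signal itself.

The toy complex pair emulates the two co-crystal structures: a two-fold
symmetric homodimeric antigen with one binder domain bound at each of its two
equivalent epitopes, one complex carrying V_H-style domains (C-terminal
attachment) and the other V_κ-style domains (N-terminal attachment), with the
inter-terminal separations placed exactly at configurable targets
(81 / 70 / 77 Å by default). Structures are poly-alanine with Cα-only
residues — sufficient because all downstream measurements use Cα positions.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .binding import KineticParams, Sensorgram, simulate_sensorgram
from .geometry import GeometryError, superpose_on_antigen
from .secmalls import MALLSCalibration, simulate_chromatogram
from .structio import Atom, Chain, Residue, Structure

__all__ = [
    "ToyComplexSpec",
    "ScenarioConfig",
    "make_toy_complex",
    "toy_roles",
    "merge_complexes",
    "make_mixing_series",
    "make_kinetics_dataset",
    "DEFAULT_SPR_CONCS_M",
]

#: analyte concentration series used for kinetics runs: 32, 8, 2, 0.5, 0.125, 0.03 nM
DEFAULT_SPR_CONCS_M = (32e-9, 8e-9, 2e-9, 0.5e-9, 0.125e-9, 0.03e-9)


# --------------------------------------------------------------------------
# toy complex structures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyComplexSpec:
    """Target geometry for the synthetic complex pair.

    ``d_vh_vh``/``d_vk_vk``/``d_cross`` are the inter-terminal Cα separations
    the construction reproduces exactly; ``d_cross`` must be at least the
    half-sum of the like-domain separations (the construction envelope of a
    planar symmetric placement). ``seed`` feeds optional coordinate jitter of
    non-terminal atoms (0 by default: bit-reproducible output).
    """

    d_vh_vh: float = 81.0
    d_vk_vk: float = 70.0
    d_cross: float = 77.0
    antigen_arm_length: float = 30.0
    antigen_residues: int = 12
    binder_domain_size: int = 8
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.d_vh_vh, self.d_vk_vk, self.d_cross) < 0:
            raise GeometryError("separations must be >= 0")
        if self.binder_domain_size < 1 or self.antigen_residues < 3:
            raise GeometryError("domain/antigen sizes too small")


def _chain_from_points(chain_id: str, points: np.ndarray, role: str) -> Chain:
    residues = [
        Residue(seq_id=i + 1, name="ALA", atoms=[Atom("CA", "C", p, 1.0, True)])
        for i, p in enumerate(points)
    ]
    return Chain(chain_id=chain_id, residues=residues, entity_role=role)


def _antigen_chains(spec: ToyComplexSpec, rng: np.random.Generator) -> list[Chain]:
    """Two-fold symmetric antigen homodimer, zig-zag arms along ±x (non-collinear)."""
    n = spec.antigen_residues
    xs = np.linspace(2.0, spec.antigen_arm_length, n)
    zig = np.where(np.arange(n) % 2 == 0, 2.0, -2.0)
    ramp = np.linspace(0.0, 3.0, n)
    arm = np.column_stack([xs, zig, ramp])
    if spec.jitter > 0:
        arm = arm + rng.normal(0.0, spec.jitter, arm.shape)
    chain_a = _chain_from_points("A", arm * np.array([-1.0, 1.0, 1.0]), "antigen")
    chain_b = _chain_from_points("B", arm, "antigen")
    return [chain_a, chain_b]


def _binder_chain(
    chain_id: str,
    terminal_xyz: np.ndarray,
    terminus: str,
    n_res: int,
    direction: np.ndarray,
) -> Chain:
    """Straight poly-ALA domain whose first/last Cα sits exactly at the target."""
    direction = direction / np.linalg.norm(direction)
    steps = np.arange(n_res)[:, None] * 3.8 * direction[None, :]
    if terminus == "c_term":
        pts = terminal_xyz - steps[::-1]  # last residue lands on the terminal point
    else:
        pts = terminal_xyz + steps  # first residue is the terminal point
    return _chain_from_points(chain_id, pts, "binder_domain")


def make_toy_complex(spec: ToyComplexSpec = ToyComplexSpec()) -> tuple[Structure, Structure]:
    """Build the synthetic complex pair sharing one antigen frame.

    Returns ``(vh_complex, vk_complex)``: the antigen chains A/B are
    coordinate-identical between the two structures (so antigen superposition
    is exact), the V_H-style chains H/I have C-terminal Cαs ``d_vh_vh`` apart,
    the V_κ-style chains K/L have N-terminal Cαs ``d_vk_vk`` apart, and the
    opposite-epitope V_H↔V_κ separation equals ``d_cross``.
    """
    half_sum = 0.5 * (spec.d_vh_vh + spec.d_vk_vk)
    dh_sq = spec.d_cross**2 - half_sum**2
    if dh_sq < -1e-9:
        raise GeometryError(
            f"impossible geometry: cross separation {spec.d_cross} Å is below the "
            f"construction envelope ({half_sum:.2f} Å) of the like-domain separations"
        )
    delta_h = math.sqrt(max(dh_sq, 0.0))
    h_vh = 20.0
    h_vk = h_vh - delta_h

    # terminal anchor points; epitope 1 on the −x arm, epitope 2 on the +x arm
    v1 = np.array([-0.5 * spec.d_vh_vh, h_vh, 0.0])
    v2 = np.array([+0.5 * spec.d_vh_vh, h_vh, 0.0])
    k1 = np.array([-0.5 * spec.d_vk_vk, h_vk, 0.0])
    k2 = np.array([+0.5 * spec.d_vk_vk, h_vk, 0.0])

    rng = np.random.default_rng(spec.seed)
    antigen_vh = _antigen_chains(spec, rng)
    # identical antigen coordinates in the partner complex: rebuild with same rng state
    rng2 = np.random.default_rng(spec.seed)
    antigen_vk = _antigen_chains(spec, rng2)

    n = spec.binder_domain_size
    up = np.array([0.0, 1.0, 0.5])
    vh_complex = Structure(
        chains=antigen_vh
        + [
            _binder_chain("H", v1, "c_term", n, up + np.array([-0.3, 0, 0])),
            _binder_chain("I", v2, "c_term", n, up + np.array([+0.3, 0, 0])),
        ],
        source_id="toy-vh-complex",
    )
    vk_complex = Structure(
        chains=antigen_vk
        + [
            _binder_chain("K", k1, "n_term", n, -up + np.array([-0.3, 0, 0])),
            _binder_chain("L", k2, "n_term", n, -up + np.array([+0.3, 0, 0])),
        ],
        source_id="toy-vk-complex",
    )
    return vh_complex, vk_complex


def toy_roles(*, tagged: bool = True) -> dict:
    """Role mapping for the merged toy model, for :func:`terminal_distances`."""
    if tagged:
        return {
            "H": ("vh", "c_term", 1),
            "I": ("vh", "c_term", 2),
            "K": ("vk", "n_term", 1),
            "L": ("vk", "n_term", 2),
        }
    return {
        "H": ("vh", "c_term"),
        "I": ("vh", "c_term"),
        "K": ("vk", "n_term"),
        "L": ("vk", "n_term"),
    }


def merge_complexes(
    complex_a: Structure,
    complex_b: Structure,
    antigen_map: Sequence[tuple[str, str]] = (("A", "A"), ("B", "B")),
) -> tuple[Structure, float]:
    """Superpose ``complex_b`` onto ``complex_a`` via the antigen and merge chains.

    Chains of ``complex_b`` already present in ``complex_a`` (the shared
    antigen) are dropped from the merged model. Returns the merged structure
    and the antigen-Cα rmsd of the superposition.
    """
    moved, sup, _warn = superpose_on_antigen(complex_a, complex_b, antigen_map)
    taken = {c.chain_id for c in complex_a.chains}
    merged = complex_a.copy()
    merged.chains.extend(c for c in moved.copy().chains if c.chain_id not in taken)
    merged.source_id = f"{complex_a.source_id}+{complex_b.source_id}"
    return merged, sup.rmsd


# --------------------------------------------------------------------------
# SEC-MALLS mixing series
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """A named binding scenario driving a simulated mixing series.

    ``scenario`` is one of ``dualdab_side_on`` (closed 1:1 and 1:2 species
    only), ``igg_network`` (ladder of n:n ring species, 2:2 dominant, as
    bivalent-IgG / bivalent-antigen mixtures produce) or ``trap_1to1``
    (1:1 complex only). ``ratios`` are binder:antigen molar mixing ratios;
    masses in kDa; ``binder_amount_ug`` scales the injections.
    """

    scenario: str = "dualdab_side_on"
    binder_mass_kda: float = 109.0
    antigen_mass_kda: float = 48.0
    ratios: tuple = ((1, 1), (1, 2), (2, 1), (4, 1))
    binder_amount_ug: float = 100.0
    noise_sd: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(rb <= 0 or rv <= 0 for rb, rv in self.ratios):
            raise ValueError("mixing ratios must be positive")
        if self.scenario not in ("dualdab_side_on", "igg_network", "trap_1to1"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


def _retention_s(mass_kda: float) -> float:
    """Simple log-linear size-exclusion retention model (seconds)."""
    return 2000.0 - 450.0 * math.log10(max(mass_kda, 1.0))


def _scenario_species(cfg: ScenarioConfig, binder_moles: float, antigen_moles: float) -> list[tuple]:
    """Occupancy assignment per scenario: (label, n_binders, n_antigens, moles)."""
    b, v = binder_moles, antigen_moles
    out: list[tuple] = []
    if cfg.scenario == "dualdab_side_on":
        # halves fill with antigen until both are occupied; no sharing, no chains
        if v >= 2 * b:
            out += [("1:2", 1, 2, b), ("0:1", 0, 1, v - 2 * b)]
        elif v >= b:
            out += [("1:2", 1, 2, v - b), ("1:1", 1, 1, 2 * b - v)]
        else:
            out += [("1:1", 1, 1, v), ("1:0", 1, 0, b - v)]
    elif cfg.scenario == "trap_1to1":
        paired = min(b, v)
        out += [("1:1", 1, 1, paired)]
        if b > paired:
            out.append(("1:0", 1, 0, b - paired))
        if v > paired:
            out.append(("0:1", 0, 1, v - paired))
    else:  # igg_network: ring ladder with the 2:2 species dominant
        paired = min(b, v)
        weights = {1: 0.10, 2: 0.50, 3: 0.25, 4: 0.15}
        for n, w in weights.items():
            out.append((f"{n}:{n}", n, n, w * paired / n))
        if b > paired:
            out.append(("1:0", 1, 0, b - paired))
        if v > paired:
            out.append(("0:1", 0, 1, v - paired))
    return [(label, nb, na, m) for (label, nb, na, m) in out if m > 1e-12]


def make_mixing_series(
    cfg: ScenarioConfig, calibration: MALLSCalibration = MALLSCalibration()
) -> list[dict]:
    """Simulate one chromatogram per mixing ratio with a ground-truth manifest.

    Each entry carries the ratio, the simulated :class:`Chromatogram`, and a
    manifest listing every injected species with its composition, mass and
    amount. Species amounts follow the scenario's occupancy rules; the
    chromatogram is then forward-simulated through the Debye-Zimm model.
    """
    runs: list[dict] = []
    for i, (rb, rv) in enumerate(cfg.ratios):
        binder_moles = 1.0
        antigen_moles = rv / rb
        species = _scenario_species(cfg, binder_moles, antigen_moles)
        # µg amounts proportional to moles × mass, scaled to the binder load
        mole_scale = cfg.binder_amount_ug / (binder_moles * cfg.binder_mass_kda)
        injected = []
        manifest = []
        for label, nb, na, moles in species:
            mass = nb * cfg.binder_mass_kda + na * cfg.antigen_mass_kda
            amount_ug = moles * mass * mole_scale
            injected.append((mass, amount_ug, _retention_s(mass), 12.0))
            manifest.append(
                {
                    "label": label,
                    "n_binders": nb,
                    "n_antigens": na,
                    "mass_kda": mass,
                    "amount_ug": amount_ug,
                    "retention_s": _retention_s(mass),
                }
            )
        chrom = simulate_chromatogram(
            injected,
            calibration,
            noise_sd=cfg.noise_sd,
            seed=cfg.seed + i,
        )
        runs.append({"ratio": (rb, rv), "chromatogram": chrom, "manifest": manifest})
    return runs


# --------------------------------------------------------------------------
# kinetics datasets
# --------------------------------------------------------------------------

def make_kinetics_dataset(
    params: KineticParams,
    concs: Sequence[float] = DEFAULT_SPR_CONCS_M,
    *,
    t_assoc: float = 240.0,
    t_diss: float = 600.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    outdir: Optional[str] = None,
) -> tuple[list[Sensorgram], dict]:
    """Forward-simulate a sensorgram series with a ground-truth manifest.

    Returns the sensorgrams and a manifest with the generating parameters
    (including the KD implied by the rates, in pM). When ``outdir`` is given,
    each sensorgram is written as a 2-column TSV and the manifest as JSON.
    """
    if not concs:
        raise ValueError("need at least one analyte concentration")
    grams = [
        simulate_sensorgram(
            params, c, t_assoc, t_diss, dt=dt, noise_sd=noise_sd, seed=seed + i
        )
        for i, c in enumerate(concs)
    ]
    manifest = {
        "ka_per_M_s": params.ka,
        "kd_per_s": params.kd,
        "rmax_ru": params.rmax,
        "kd_pm": params.kd / params.ka * 1e12,
        "concs_M": [float(c) for c in concs],
        "t_assoc_s": t_assoc,
        "t_diss_s": t_diss,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for i, g in enumerate(grams):
            path = os.path.join(outdir, f"sensorgram_{i:02d}.tsv")
            with open(path, "w") as fh:
                fh.write(f"# analyte_conc_M\t{g.analyte_conc:.6g}\n")
                fh.write(f"# t_assoc_end_s\t{g.t_assoc_end:.6g}\n")
                fh.write("# time_s\tresponse_ru\n")
                for t, r in zip(g.time, g.response):
                    fh.write(f"{t:.10g}\t{r:.10g}\n")
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return grams, manifest
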