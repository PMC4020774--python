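"""Three-compartment VEGF / anti-VEGF kinetic-transport model.

Compartments: normal tissue, blood, diseased tissue. Free VEGF is secreted
in each compartment, binds cell-surface receptor pools (mass action, one
binding site per pre-dimerized receptor), is buffered by GAG sites in the
tissue interstitia, exchanges with blood via vascular permeability and
lymphatic drainage, and is cleared from blood. An anti-VEGF agent is given
as a t = 0 bolus into blood, binds free VEGF into a soluble complex, and is
cleared from blood.

Receptor pools carry surface levels in receptors/cell; insertion and
internalization balance so that the drug-free steady-state surface level
(free + ligand-bound) equals ``insertion_rate / k_int``. Endothelial cell
types expose a luminal surface to blood and an abluminal surface to their
tissue compartment, with equal receptor levels on both surfaces.

Parameter values are order-of-magnitude literature-plausible defaults
declared in :func:`default_model`; absolute concentrations are not
reproduction targets — directions and structure are.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.constants import Avogadro
from scipy.integrate import solve_ivp
from scipy.optimize import root

COMPARTMENTS = ("normal", "blood", "diseased")
TISSUES = ("normal", "diseased")
RECEPTORS = ("VEGFR1", "VEGFR2", "NRP1")

THREE_WEEKS_S = 21 * 86400.0


class ModelError(RuntimeError):
    """Raised on invalid model configuration or failed integration."""


def receptors_per_cell_to_concentration(level: float, cells: float, volume_l: float) -> float:
    """Convert a per-cell receptor count to a compartment concentration (pM)."""
    if level < 0 or cells < 0:
        raise ValueError("level and cells must be >= 0")
    if volume_l <= 0:
        raise ValueError("volume must be > 0 L")
    return level * cells / (Avogadro * volume_l) * 1e12


@dataclass
class ReceptorPool:
    """One receptor species on one surface of one cell type.

    ``level`` is the target drug-free steady-state surface density
    (receptors per cell surface). ``insertion_override`` (receptors/cell/s),
    when set, decouples the insertion rate from ``level``.
    """

    cell_type: str
    receptor: str
    surface: str  # luminal | abluminal | whole
    compartment: str
    cells: float
    level: float
    k_on: float  # 1/(pM s)
    k_off: float  # 1/s
    k_int: float  # 1/s
    insertion_override: float | None = None

    @property
    def insertion_rate(self) -> float:
        """Receptor insertion rate, receptors/cell/s (s_R = level * k_int)."""
        if self.insertion_override is not None:
            return self.insertion_override
        return self.level * self.k_int

    @property
    def kd(self) -> float:
        return self.k_off / self.k_on


@dataclass
class CompartmentModel:
    volumes: dict[str, float]  # L
    secretion: dict[str, float]  # pM/s of free VEGF per compartment
    clearance_vegf: float  # 1/s, blood
    clearance_drug: float  # 1/s, blood (free drug and complex)
    k_perm: dict[str, float]  # 1/s, tissue-side blood<->tissue exchange
    k_lymph: dict[str, float]  # 1/s, tissue -> blood drainage
    drug_kon: float  # 1/(pM s)
    drug_koff: float  # 1/s
    gag_sites: dict[str, float]  # pM of binding sites per tissue
    gag_kon: float
    gag_koff: float
    pools: list[ReceptorPool] = field(default_factory=list)

    def validate(self) -> None:
        for c in COMPARTMENTS:
            if self.volumes.get(c, 0) <= 0:
                raise ModelError(f"volume of {c!r} must be > 0")
            if self.secretion.get(c, 0) < 0:
                raise ModelError("secretion rates must be >= 0")
        rates = [self.clearance_vegf, self.clearance_drug, self.drug_kon,
                 self.drug_koff, self.gag_kon, self.gag_koff]
        rates += [self.k_perm[t] for t in TISSUES] + [self.k_lymph[t] for t in TISSUES]
        if any(r < 0 for r in rates):
            raise ModelError("all rates must be >= 0")
        for p in self.pools:
            if p.compartment not in COMPARTMENTS:
                raise ModelError(f"pool in unknown compartment {p.compartment!r}")
            if min(p.k_on, p.k_off, p.k_int, p.level, p.cells) < 0:
                raise ModelError("pool rates, level and cells must be >= 0")

    def copy(self) -> "CompartmentModel":
        return copy.deepcopy(self)

    def pools_for(self, cell_type: str, receptor: str) -> list[ReceptorPool]:
        return [p for p in self.pools if p.cell_type == cell_type and p.receptor == receptor]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CompartmentModel":
        d = copy.deepcopy(d)
        d["pools"] = [ReceptorPool(**p) for p in d.get("pools", [])]
        model = cls(**d)
        model.validate()
        return model


@dataclass(frozen=True)
class DoseSchedule:
    """A t = 0 anti-VEGF bolus into blood and the simulation horizon."""

    bolus_pm: float = 1.0e5
    horizon_s: float = THREE_WEEKS_S

    def __post_init__(self) -> None:
        if self.bolus_pm < 0:
            raise ValueError("bolus must be >= 0")
        if self.horizon_s <= 0:
            raise ValueError("horizon must be > 0")


@dataclass
class SimulationResult:
    time: np.ndarray  # s
    vegf: dict[str, np.ndarray]  # pM per compartment
    drug: dict[str, np.ndarray]
    complex: dict[str, np.ndarray]
    pre_steady_state: dict[str, float]  # drug-free free-VEGF per compartment
    horizon_s: float

    def endpoint_vegf(self) -> dict[str, float]:
        return {c: float(self.vegf[c][-1]) for c in COMPARTMENTS}


@dataclass
class FoldChangeReport:
    """Per-compartment relative change in free VEGF over the horizon.

    FC = (V(horizon) - V(0-)) / V(0-), with V(0-) the pre-injection steady
    state; an increase after injection is positive. ``normalized`` divides
    by the control run's FC.
    """

    fold_change: dict[str, float]
    normalized: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {"fold_change": self.fold_change, "normalized": self.normalized}


class StateIndex:
    """Maps model species to positions in the flat ODE state vector."""

    def __init__(self, model: CompartmentModel):
        self.v = {c: i for i, c in enumerate(COMPARTMENTS)}
        self.a = {c: 3 + i for i, c in enumerate(COMPARTMENTS)}
        self.c = {c: 6 + i for i, c in enumerate(COMPARTMENTS)}
        self.gag = {t: 9 + i for i, t in enumerate(TISSUES)}
        self.r: list[int] = []
        self.vr: list[int] = []
        base = 11
        for i, _ in enumerate(model.pools):
            self.r.append(base + 2 * i)
            self.vr.append(base + 2 * i + 1)
        self.size = base + 2 * len(model.pools)


def state_index(model: CompartmentModel) -> StateIndex:
    return StateIndex(model)


def _pool_concentrations(model: CompartmentModel):
    """Per-pool (R_ss concentration pM, insertion pM/s) in its compartment."""
    out = []
    for p in model.pools:
        vol = model.volumes[p.compartment]
        r_conc = receptors_per_cell_to_concentration(p.level, p.cells, vol)
        s_conc = receptors_per_cell_to_concentration(p.insertion_rate, p.cells, vol)
        out.append((r_conc, s_conc))
    return out


def make_rhs(model: CompartmentModel):
    """Build the mass-action right-hand side f(t, y) for this model."""
    model.validate()
    idx = StateIndex(model)
    vols = model.volumes
    pool_conc = _pool_concentrations(model)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        V = {c: y[idx.v[c]] for c in COMPARTMENTS}
        A = {c: y[idx.a[c]] for c in COMPARTMENTS}
        C = {c: y[idx.c[c]] for c in COMPARTMENTS}

        for c in COMPARTMENTS:
            dy[idx.v[c]] += model.secretion[c]
            # VEGF + drug <-> complex
            rate = model.drug_kon * V[c] * A[c] - model.drug_koff * C[c]
            dy[idx.v[c]] -= rate
            dy[idx.a[c]] -= rate
            dy[idx.c[c]] += rate

        # blood clearance
        dy[idx.v["blood"]] -= model.clearance_vegf * V["blood"]
        dy[idx.a["blood"]] -= model.clearance_drug * A["blood"]
        dy[idx.c["blood"]] -= model.clearance_drug * C["blood"]

        # transport: vascular permeability (both ways) + lymphatic drainage
        for t_name in TISSUES:
            ratio = vols[t_name] / vols["blood"]
            kp, kl = model.k_perm[t_name], model.k_lymph[t_name]
            for sp in (idx.v, idx.a, idx.c):
                flux = kp * (y[sp["blood"]] - y[sp[t_name]])  # tissue-side, pM/s
                dy[sp[t_name]] += flux
                dy[sp["blood"]] -= flux * ratio
                drain = kl * y[sp[t_name]]
                dy[sp[t_name]] -= drain
                dy[sp["blood"]] += drain * ratio

        # GAG buffering in tissue interstitium
        for t_name in TISSUES:
            gv = y[idx.gag[t_name]]
            free_sites = model.gag_sites[t_name] - gv
            rate = model.gag_kon * V[t_name] * free_sites - model.gag_koff * gv
            dy[idx.v[t_name]] -= rate
            dy[idx.gag[t_name]] += rate

        # receptor pools: insertion, internalization, VEGF binding
        for i, p in enumerate(model.pools):
            r, vr = y[idx.r[i]], y[idx.vr[i]]
            s_conc = pool_conc[i][1]
            bind = p.k_on * V[p.compartment] * r - p.k_off * vr
            dy[idx.r[i]] += s_conc - p.k_int * r - bind
            dy[idx.vr[i]] += bind - p.k_int * vr
            dy[idx.v[p.compartment]] -= bind
        return dy

    return rhs, idx


def initial_state(model: CompartmentModel) -> np.ndarray:
    """Zero ligand everywhere; receptors at their insertion/internalization level."""
    idx = StateIndex(model)
    y0 = np.zeros(idx.size)
    for i, (p, (r_conc, s_conc)) in enumerate(zip(model.pools, _pool_concentrations(model))):
        y0[idx.r[i]] = s_conc / p.k_int if p.k_int > 0 else r_conc
    return y0


def integrate(
    model: CompartmentModel,
    y0: np.ndarray,
    horizon_s: float,
    n_points: int = 400,
    rtol: float = 1e-8,
):
    """Stiff integration of the model from ``y0``; returns (t, Y[state, t])."""
    rhs_fn, _ = make_rhs(model)
    t_eval = np.linspace(0.0, horizon_s, n_points)
    sol = solve_ivp(
        rhs_fn,
        (0.0, horizon_s),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=1e-12,
    )
    if not sol.success:
        raise ModelError(f"integration failed: {sol.message}")
    return sol.t, sol.y


def steady_state(
    model: CompartmentModel, relax_s: float = 2.0e8, rel_tol: float = 1e-9
) -> np.ndarray:
    """Drug-free steady state: long relaxation then algebraic root polish."""
    rhs_fn, _ = make_rhs(model)
    y0 = initial_state(model)
    sol = solve_ivp(rhs_fn, (0.0, relax_s), y0, method="LSODA", rtol=1e-10, atol=1e-14)
    if not sol.success:
        raise ModelError(f"steady-state relaxation failed: {sol.message}")
    y_relaxed = sol.y[:, -1]

    res = root(lambda y: rhs_fn(0.0, y), y_relaxed, method="hybr", tol=1e-14)
    y_ss = res.x if res.success else y_relaxed
    y_ss = np.where(np.abs(y_ss) < 1e-12, np.maximum(y_ss, 0.0), y_ss)
    if np.any(y_ss < 0):
        raise ModelError("steady state contains negative concentrations")

    scale = max(float(np.max(np.abs(y_ss))), 1e-30)
    resid = float(np.max(np.abs(rhs_fn(0.0, y_ss))))
    if resid > rel_tol * scale:
        raise ModelError(
            f"steady state not verified: max |dY/dt| = {resid:.3e} "
            f"exceeds {rel_tol:.0e} relative"
        )
    return y_ss


def simulate(
    model: CompartmentModel, dose: DoseSchedule = DoseSchedule(), n_points: int = 400
) -> SimulationResult:
    """Drug-free steady state, t = 0 bolus into blood, integrate to horizon."""
    idx = StateIndex(model)
    y_ss = steady_state(model)
    y0 = y_ss.copy()
    y0[idx.a["blood"]] += dose.bolus_pm
    t, Y = integrate(model, y0, dose.horizon_s, n_points=n_points)

    if Y.min() < -1e-6 * max(Y.max(), 1.0):
        raise ModelError(f"negative state beyond tolerance: min = {Y.min():.3e}")
    Y = np.maximum(Y, 0.0)
    return SimulationResult(
        time=t,
        vegf={c: Y[idx.v[c]] for c in COMPARTMENTS},
        drug={c: Y[idx.a[c]] for c in COMPARTMENTS},
        complex={c: Y[idx.c[c]] for c in COMPARTMENTS},
        pre_steady_state={c: float(y_ss[idx.v[c]]) for c in COMPARTMENTS},
        horizon_s=dose.horizon_s,
    )


def fold_change(sim: SimulationResult, control_sim: SimulationResult | None = None) -> FoldChangeReport:
    """FC = (V(horizon) - V(0-)) / V(0-) per compartment, optionally normalized."""
    if control_sim is not None and not math.isclose(sim.horizon_s, control_sim.horizon_s):
        raise ValueError("simulations must share the same horizon")
    fc = {}
    for c in COMPARTMENTS:
        pre = sim.pre_steady_state[c]
        if pre == 0:
            raise ValueError(f"pre-injection steady state is 0 in {c!r}: FC undefined")
        fc[c] = (float(sim.vegf[c][-1]) - pre) / pre
    normalized = None
    if control_sim is not None:
        control_fc = fold_change(control_sim).fold_change
        normalized = {}
        for c in COMPARTMENTS:
            if control_fc[c] == 0:
                raise ValueError(f"control fold change is 0 in {c!r}")
            normalized[c] = fc[c] / control_fc[c]
    return FoldChangeReport(fold_change=fc, normalized=normalized)


ENDOTHELIAL_TYPES = ("healthy_ec", "tec")


def apply_receptor_update(
    model: CompartmentModel, cell_type: str, receptor: str, whole_cell_level: float
) -> CompartmentModel:
    """Return a copy with one cell type's receptor set to a whole-cell level.

    Endothelial whole-cell levels split equally between the luminal (blood)
    and abluminal (tissue) surfaces; other cell types carry the whole level
    on their single surface. Insertion rates follow the new level
    (s_R = level * k_int), so the drug-free steady state equals the request.
    """
    if whole_cell_level < 0:
        raise ValueError("receptor level must be >= 0")
    updated = model.copy()
    pools = updated.pools_for(cell_type, receptor)
    if not pools:
        known = sorted({(p.cell_type, p.receptor) for p in model.pools})
        raise ModelError(
            f"no pool for cell type {cell_type!r} receptor {receptor!r}; known: {known}"
        )
    per_surface = whole_cell_level / 2.0 if cell_type in ENDOTHELIAL_TYPES else whole_cell_level
    for p in pools:
        p.level = per_surface
        p.insertion_override = None
    return updated


def set_insertion_rate(
    model: CompartmentModel, cell_type: str, receptor: str, rate_per_cell_s: float
) -> CompartmentModel:
    """Return a copy with the pool's insertion rate pinned (receptors/cell/s)."""
    if rate_per_cell_s < 0:
        raise ValueError("insertion rate must be >= 0")
    updated = model.copy()
    pools = updated.pools_for(cell_type, receptor)
    if not pools:
        raise ModelError(f"no pool for {cell_type!r}/{receptor!r}")
    for p in pools:
        p.insertion_override = rate_per_cell_s
    return updated


def sensitivity_scan(
    model: CompartmentModel,
    parameter: str,
    grid,
    dose: DoseSchedule = DoseSchedule(),
    cell_type: str | None = None,
    receptor: str | None = None,
) -> list[dict]:
    """Simulate and report fold changes along a parameter grid.

    ``parameter`` is ``receptor_level`` (receptors/cell, whole cell),
    ``insertion_rate`` (receptors/cell/s) — both requiring ``cell_type`` and
    ``receptor`` — or a scalar model attribute name such as
    ``clearance_vegf``.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("grid values must be >= 0")
    control = simulate(model, dose)
    rows = []
    for g in grid:
        if parameter == "receptor_level":
            m = apply_receptor_update(model, cell_type, receptor, float(g))
        elif parameter == "insertion_rate":
            m = set_insertion_rate(model, cell_type, receptor, float(g))
        else:
            if not hasattr(model, parameter):
                raise ModelError(f"unknown scalar parameter {parameter!r}")
            m = model.copy()
            setattr(m, parameter, float(g))
        sim = simulate(m, dose)
        report = fold_change(sim, control)
        rows.append(
            {
                "parameter": parameter,
                "value": float(g),
                "pre_steady_state": sim.pre_steady_state,
                "endpoint_vegf": sim.endpoint_vegf(),
                "fold_change": report.fold_change,
                "normalized": report.normalized,
            }
        )
    return rows


# control whole-cell surface levels on endothelium (receptors/cell)
CONTROL_VEGFR1_PER_CELL = 1100.0
CONTROL_VEGFR2_PER_CELL = 700.0
CONTROL_NRP1_PER_CELL = 25000.0


def default_model() -> CompartmentModel:
    """Order-of-magnitude default parameterization of the tumor-bearing model.

    Paper-anchored structure: three compartments; control endothelial levels
    of 1,100 VEGFR1/cell and 700 VEGFR2/cell split 50/50 between luminal and
    abluminal surfaces; VEGFR1 binds VEGF with higher affinity than VEGFR2;
    NRP1 acts as a binding sink. Rates and volumes are literature-plausible
    defaults, not a reproduction of any published parameter table.
    """
    volumes = {"normal": 10.0, "blood": 5.0, "diseased": 1.0}
    kin = {
        # receptor: (k_on 1/(pM s), k_off 1/s) -> Kd(R1)=3.3 pM < Kd(R2)=100 pM
        "VEGFR1": (3.0e-5, 1.0e-4),
        "VEGFR2": (1.0e-5, 1.0e-3),
        "NRP1": (1.0e-6, 1.0e-3),
    }
    k_int = 1.0e-4

    def ec_pools(cell_type: str, tissue: str, cells: float, levels: dict[str, float]):
        pools = []
        for rec, whole in levels.items():
            for surface, comp in (("luminal", "blood"), ("abluminal", tissue)):
                pools.append(
                    ReceptorPool(
                        cell_type=cell_type,
                        receptor=rec,
                        surface=surface,
                        compartment=comp,
                        cells=cells,
                        level=whole / 2.0,
                        k_on=kin[rec][0],
                        k_off=kin[rec][1],
                        k_int=k_int,
                    )
                )
        return pools

    def parenchymal_pools(cell_type: str, comp: str, cells: float, levels: dict[str, float]):
        return [
            ReceptorPool(
                cell_type=cell_type,
                receptor=rec,
                surface="whole",
                compartment=comp,
                cells=cells,
                level=level,
                k_on=kin[rec][0],
                k_off=kin[rec][1],
                k_int=k_int,
            )
            for rec, level in levels.items()
        ]

    ec_levels = {
        "VEGFR1": CONTROL_VEGFR1_PER_CELL,
        "VEGFR2": CONTROL_VEGFR2_PER_CELL,
        "NRP1": CONTROL_NRP1_PER_CELL,
    }
    pools = (
        ec_pools("healthy_ec", "normal", 2.5e11, ec_levels)
        + ec_pools("tec", "diseased", 1.0e9, ec_levels)
        + parenchymal_pools(
            "myocyte", "normal",
            1.5e11, {"VEGFR1": CONTROL_VEGFR1_PER_CELL, "VEGFR2": CONTROL_VEGFR2_PER_CELL},
        )
        + parenchymal_pools(
            "tumor", "diseased",
            1.0e10, {"VEGFR1": CONTROL_VEGFR1_PER_CELL, "VEGFR2": CONTROL_VEGFR2_PER_CELL},
        )
    )
    model = CompartmentModel(
        volumes=volumes,
        secretion={"normal": 2.0e-3, "blood": 1.0e-4, "diseased": 5.0e-3},
        clearance_vegf=2.0e-4,
        clearance_drug=4.0e-7,  # ~3-week antibody half-life
        k_perm={"normal": 3.0e-5, "diseased": 1.0e-4},  # leaky tumor vasculature
        k_lymph={"normal": 2.0e-5, "diseased": 2.0e-5},
        drug_kon=5.0e-5,
        drug_koff=5.0e-5,  # Kd = 1 pM
        gag_sites={"normal": 1.0e4, "diseased": 1.0e4},
        gag_kon=1.0e-6,
        gag_koff=1.0e-2,  # Kd = 10 nM, weak interstitial buffer
        pools=pools,
    )
    model.validate()
    return model
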