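"""Synthetic resazurin drug-screen generator with known ground truth.

The generator produces long-format screens that emulate the phenomenology of
a 96-well resazurin viability assay:

* exponential cell growth with cell-line-specific doubling times (optionally
  logistic-capped by a carrying capacity),
* drug effect parameterized directly in growth-rate-inhibition (GR) space and
  pushed forward to end-point cell counts — the exact inverse of the analysis
  transform, so parameter recovery is well posed,
* absorbance signal proportional to viable cell number plus a background
  offset,
* DMSO vehicle toxicity (Hill-shaped viability factor),
* evaporation-driven concentration drift of stored drug dilutions,
* multiplicative perimeter-well signal inflation (edge effect),
* multiplicative replicate noise (Normal multiplier truncated at zero).

Determinism: every stochastic draw flows from a counter-based stream keyed by
(master seed, plate id, well index), so regenerating with the same SimTruth
is bit-identical and adding plates never perturbs existing wells.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .io import REQUIRED_COLUMNS, Screen, PlateRead, DMSO_DECIMALS
from .wells import WellAddress, WellRole, all_wells, interior_wells


# ---------------------------------------------------------------------------
# truth parameter containers

@dataclass
class CellLineTruth:
    """Growth parameters for one simulated cell line."""

    doubling_time_h: float
    n0: float = 7.5e3          # cells seeded per well
    capacity: float | None = None  # logistic plateau; None = pure exponential

    def validate(self, errors: list[str], name: str) -> None:
        if self.doubling_time_h <= 0:
            errors.append(f"cell_lines[{name}].doubling_time_h must be > 0")
        if self.n0 <= 0:
            errors.append(f"cell_lines[{name}].n0 must be > 0")
        if self.capacity is not None and self.capacity <= self.n0:
            errors.append(f"cell_lines[{name}].capacity must exceed n0")


@dataclass
class GRCurveTruth:
    """Ground-truth GR dose-response curve for one (cell line, drug) pair.

    GR(c) = gr_inf + (1 - gr_inf) / (1 + (c / gec50)^h_gr), so GR(0) = 1
    (no effect) and GR -> gr_inf at saturating dose.
    """

    gr_inf: float
    gec50: float
    h_gr: float

    def __call__(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(c > 0, (c / self.gec50) ** self.h_gr, 0.0)
        return self.gr_inf + (1.0 - self.gr_inf) / (1.0 + ratio)

    def validate(self, errors: list[str], name: str) -> None:
        if not (-1.0 <= self.gr_inf <= 1.0):
            errors.append(f"drugs[{name}].gr_inf must lie in [-1, 1]")
        if self.gec50 <= 0:
            errors.append(f"drugs[{name}].gec50 must be > 0")
        if self.h_gr <= 0:
            errors.append(f"drugs[{name}].h_gr must be > 0")


@dataclass
class DosePlan:
    """Concentration grid and replication plan."""

    top: float = 10_000.0
    fold: float = 2.0
    n_doses: int = 9
    replicates: int = 3
    conc_unit: str = "nM"
    dmso_top_pct: float = 0.5  # DMSO % at the top dose; scales with dose

    def validate(self, errors: list[str]) -> None:
        if self.top <= 0:
            errors.append("plan.top must be > 0")
        if self.fold <= 1:
            errors.append("plan.fold must be > 1")
        if self.n_doses < 1:
            errors.append("plan.n_doses must be >= 1")
        if self.replicates < 1:
            errors.append("plan.replicates must be >= 1")
        if not (0 <= self.dmso_top_pct <= 100):
            errors.append("plan.dmso_top_pct must be a percentage")


@dataclass
class SimTruth:
    """Full generative parameter set of a simulated screen."""

    cell_lines: dict[str, CellLineTruth]
    drugs: dict[tuple[str, str], GRCurveTruth]  # (cell_line, drug) -> curve
    plan: DosePlan = field(default_factory=DosePlan)
    n_experiments: int = 3
    treat_time_h: float = 24.0
    plating_to_treat_h: float = 24.0  # cells grow this long before t=0
    alpha: float = 1e-4   # absorbance a.u. per cell
    beta: float = 0.05    # background absorbance a.u.
    noise_cv: float = 0.05
    edge_inflation: float = 0.10
    dmso_d50: float = 2.0    # % (v/v) DMSO at half viability
    dmso_hill: float = 2.0
    evaporation_rate: float = 0.0  # per-day fractional concentration increase
    storage_days: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        errors: list[str] = []
        if not self.cell_lines:
            errors.append("cell_lines must not be empty")
        for name, cl in self.cell_lines.items():
            cl.validate(errors, name)
        for key, curve in self.drugs.items():
            cell_line = key[0]
            if cell_line not in self.cell_lines:
                errors.append(f"drugs[{key}] references unknown cell line")
            curve.validate(errors, str(key))
        self.plan.validate(errors)
        for fname in ("alpha", "noise_cv", "edge_inflation",
                      "evaporation_rate", "storage_days"):
            if getattr(self, fname) < 0:
                errors.append(f"{fname} must be >= 0")
        if self.alpha <= 0:
            errors.append("alpha must be > 0")
        if self.beta < 0:
            errors.append("beta must be >= 0")
        if self.dmso_d50 <= 0 or self.dmso_hill <= 0:
            errors.append("dmso_d50 and dmso_hill must be > 0")
        if self.n_experiments < 1:
            errors.append("n_experiments must be >= 1")
        if self.treat_time_h < 0 or self.plating_to_treat_h < 0:
            errors.append("times must be >= 0")
        if errors:
            raise ValidationError("invalid SimTruth: " + "; ".join(errors))

    # -- YAML-friendly (de)serialization -----------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_lines"] = {k: asdict(v) for k, v in self.cell_lines.items()}
        d["drugs"] = {
            cl: {drug: asdict(curve) for (c, drug), curve in self.drugs.items() if c == cl}
            for cl in self.cell_lines
        }
        d["plan"] = asdict(self.plan)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        d = dict(d)
        d["cell_lines"] = {k: CellLineTruth(**v) for k, v in d["cell_lines"].items()}
        d["drugs"] = {
            (cl, drug): GRCurveTruth(**curve)
            for cl, per_drug in d["drugs"].items()
            for drug, curve in per_drug.items()
        }
        d["plan"] = DosePlan(**d["plan"])
        return cls(**d)


@dataclass
class SimulatedScreen:
    screen: Screen
    truth: SimTruth


# ---------------------------------------------------------------------------
# elementary generative pieces

def dilution_series(top: float, fold: float, n: int) -> np.ndarray:
    """Descending geometric series top, top/fold, ..., top/fold^(n-1)."""
    if top <= 0 or n < 1:
        raise DomainError("dilution_series requires top > 0 and n >= 1")
    if fold <= 1:
        raise DomainError("dilution_series requires fold > 1")
    return top / fold ** np.arange(n, dtype=float)


def grow(n0: float, td: float, t: float, capacity: float | None = None) -> float:
    """Cell count after ``t`` hours of growth with doubling time ``td``.

    Pure exponential N0 * 2^(t/Td), or logistic with plateau ``capacity``
    (same initial rate, monotone nondecreasing, bounded by capacity).
    """
    if n0 <= 0 or td <= 0:
        raise DomainError("grow requires n0 > 0 and td > 0")
    if t < 0:
        raise DomainError("grow requires t >= 0")
    if capacity is None:
        return float(n0 * 2.0 ** (t / td))
    r = np.log(2.0) / td
    k = float(capacity)
    return float(k / (1.0 + (k / n0 - 1.0) * np.exp(-r * t)))


def gr_forward(x0: float, x_ctrl: float, gr: float) -> float:
    """Cell count with growth-rate inhibition ``gr``, the inverse of the GR
    transform: x = x0 * 2^( log2(1+GR) * log2(x_ctrl/x0) ).

    GR = 1 returns x_ctrl (no effect); GR = 0 returns x0 (cytostasis);
    GR -> -1 is the complete-kill limit and is outside the domain.
    """
    if not (x_ctrl > x0 > 0):
        raise DomainError("gr_forward requires x_ctrl > x0 > 0")
    if gr <= -1.0:
        raise DomainError("gr_forward requires GR > -1 (complete kill is a limit)")
    return float(x0 * 2.0 ** (np.log2(1.0 + gr) * np.log2(x_ctrl / x0)))


def dmso_viability_factor(dmso_pct: float, d50: float, h: float) -> float:
    """Fraction of control growth surviving the solvent alone:
    1 / (1 + (dmso/d50)^h); equals 1 at 0% and 0.5 at d50."""
    if dmso_pct < 0:
        raise DomainError("dmso_pct must be >= 0")
    if dmso_pct == 0:
        return 1.0
    return float(1.0 / (1.0 + (dmso_pct / d50) ** h))


def effective_concentration(c: float, r: float, days: float) -> float:
    """Concentration after evaporation during plate storage: c * (1+r)^days."""
    if c < 0 or r < 0 or days < 0:
        raise DomainError("effective_concentration requires nonnegative arguments")
    return float(c * (1.0 + r) ** days)


# ---------------------------------------------------------------------------
# deterministic per-well noise streams

def _well_rng(seed: int, plate_id: str, well: WellAddress) -> np.random.Generator:
    plate_key = zlib.crc32(plate_id.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), plate_key, well.index])
    )


def _noise(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    return float(max(0.0, rng.normal(1.0, cv)))


# ---------------------------------------------------------------------------
# screen assembly

def _record(plate_id, well, role, cell_line, drug, conc, unit, dmso, treat_h,
            read_h, signal, experiment):
    return {
        "plate_id": plate_id, "well": str(well), "row": well.row, "col": well.col,
        "role": role.value, "cell_line": cell_line, "drug": drug,
        "conc": float(conc), "conc_unit": unit, "dmso_pct": float(dmso),
        "treat_time_h": float(treat_h), "read_time_h": float(read_h),
        "signal": float(signal), "experiment": experiment,
    }


def simulate_screen(truth: SimTruth) -> SimulatedScreen:
    """Simulate a full screen per the generative model in the module docstring.

    Per (experiment, cell line, drug) an end-point plate is laid out on the 60
    interior wells — replicated dose series, matched DMSO vehicle controls
    (one control triplet per dose's solvent level) and background wells — with
    PBS-filled, role=excluded perimeter wells. Per (experiment, cell line) a
    sister plate read at treatment time t=0 carries the untreated_reference
    wells used as the GR x0 anchor.
    """
    truth.validate()
    plan = truth.plan
    concs = dilution_series(plan.top, plan.fold, plan.n_doses)
    dmso_levels = np.round(plan.dmso_top_pct * concs / plan.top, DMSO_DECIMALS)
    rows: list[dict] = []

    t0 = truth.plating_to_treat_h
    t_end = t0 + truth.treat_time_h
    read_end = t_end  # read immediately after treatment window

    for exp in range(1, truth.n_experiments + 1):
        exp_id = f"E{exp}"
        for cell_line, cl in truth.cell_lines.items():
            x0_count = grow(cl.n0, cl.doubling_time_h, t0, cl.capacity)

            # sister t0 plate: untreated_reference + background, read at t=0
            pid0 = f"{exp_id}_{cell_line}_T0"
            ref_wells = interior_wells()[:6]
            bg_wells0 = interior_wells()[6:10]
            for w in ref_wells:
                rng = _well_rng(truth.seed, pid0, w)
                s = (truth.alpha * x0_count + truth.beta) * _noise(rng, truth.noise_cv)
                rows.append(_record(pid0, w, WellRole.UNTREATED_REFERENCE, cell_line,
                                    "", 0.0, plan.conc_unit, 0.0,
                                    truth.treat_time_h, t0, s, exp_id))
            for w in bg_wells0:
                rng = _well_rng(truth.seed, pid0, w)
                s = truth.beta * _noise(rng, truth.noise_cv)
                rows.append(_record(pid0, w, WellRole.BACKGROUND, "", "", 0.0,
                                    plan.conc_unit, 0.0, truth.treat_time_h,
                                    t0, s, exp_id))

            for (cl_name, drug), curve in truth.drugs.items():
                if cl_name != cell_line:
                    continue
                pid = f"{exp_id}_{cell_line}_{drug}"
                interior = interior_wells()
                n_t = plan.n_doses * plan.replicates
                if 2 * n_t + 1 > len(interior):
                    raise ValidationError(
                        "dose plan does not fit on 60 interior wells "
                        f"({plan.n_doses} doses x {plan.replicates} replicates)"
                    )
                treated_wells = interior[:n_t]
                vehicle_wells = interior[n_t:2 * n_t]
                bg_wells = interior[2 * n_t:min(len(interior), 2 * n_t + 6)]

                ctrl_grow = grow(cl.n0, cl.doubling_time_h, read_end, cl.capacity)

                k = 0
                for conc, dmso in zip(concs, dmso_levels):
                    c_eff = effective_concentration(
                        conc, truth.evaporation_rate, truth.storage_days)
                    gr_t = float(curve(c_eff))
                    x_ctrl = ctrl_grow * dmso_viability_factor(
                        float(dmso), truth.dmso_d50, truth.dmso_hill)
                    if x_ctrl <= x0_count:
                        raise ValidationError(
                            f"vehicle control at {dmso}% DMSO does not outgrow the "
                            f"t=0 reference for {cell_line}; GR is undefined"
                        )
                    x_treated = gr_forward(x0_count, x_ctrl, max(gr_t, -1 + 1e-12))
                    for _ in range(plan.replicates):
                        w = treated_wells[k]
                        rng = _well_rng(truth.seed, pid, w)
                        s = (truth.alpha * x_treated + truth.beta) * _noise(rng, truth.noise_cv)
                        rows.append(_record(pid, w, WellRole.TREATED, cell_line, drug,
                                            conc, plan.conc_unit, dmso,
                                            truth.treat_time_h, read_end, s, exp_id))
                        wv = vehicle_wells[k]
                        rngv = _well_rng(truth.seed, pid, wv)
                        sv = (truth.alpha * x_ctrl + truth.beta) * _noise(rngv, truth.noise_cv)
                        rows.append(_record(pid, wv, WellRole.VEHICLE_CONTROL, cell_line,
                                            "", 0.0, plan.conc_unit, dmso,
                                            truth.treat_time_h, read_end, sv, exp_id))
                        k += 1
                for w in bg_wells:
                    rng = _well_rng(truth.seed, pid, w)
                    s = truth.beta * _noise(rng, truth.noise_cv)
                    rows.append(_record(pid, w, WellRole.BACKGROUND, "", "", 0.0,
                                        plan.conc_unit, 0.0, truth.treat_time_h,
                                        read_end, s, exp_id))
                # PBS-filled perimeter, retained with role=excluded; edge
                # inflation acts on whatever signal the well produces
                for w in all_wells():
                    if not w.is_perimeter:
                        continue
                    rng = _well_rng(truth.seed, pid, w)
                    s = truth.beta * (1.0 + truth.edge_inflation) * _noise(rng, truth.noise_cv)
                    rows.append(_record(pid, w, WellRole.EXCLUDED, "", "", 0.0,
                                        plan.conc_unit, 0.0, truth.treat_time_h,
                                        read_end, s, exp_id))

    df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS + ["experiment"])
    return SimulatedScreen(Screen(df), truth)


def simulate_uniform_plate(
    n0: float = 7.5e3,
    doubling_time_h: float = 26.0,
    t_h: float = 48.0,
    alpha: float = 1e-4,
    beta: float = 0.05,
    noise_cv: float = 0.05,
    edge_inflation: float = 0.0,
    seed: int = 0,
    plate_id: str = "UNIFORM",
) -> PlateRead:
    """A plate with untreated cells in all 96 wells — the layout used to probe
    the edge effect, where perimeter wells must carry signal to compare against
    the interior."""
    n = grow(n0, doubling_time_h, t_h)
    recs = []
    for w in all_wells():
        rng = _well_rng(seed, plate_id, w)
        s = (alpha * n + beta) * _noise(rng, noise_cv)
        if w.is_perimeter:
            s *= 1.0 + edge_inflation
        recs.append(_record(plate_id, w, WellRole.TREATED, "CL", "", 0.0, "nM",
                            0.0, 0.0, t_h, s, "E1"))
    return PlateRead(plate_id, t_h, pd.DataFrame(recs))


def simulate_growth_course(
    doubling_time_h: float,
    n_days: int = 5,
    replicates: int = 3,
    n0: float = 7.5e3,
    capacity: float | None = None,
    alpha: float = 1e-4,
    beta: float = 0.05,
    noise_cv: float = 0.03,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Daily resazurin reads of untreated wells for doubling-time estimation.

    Returns (times_h, background_corrected_signals), one signal per
    (day, replicate); times repeat per replicate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x67726f77]))
    times, signals = [], []
    for day in range(1, n_days + 1):
        t = 24.0 * day
        n = grow(n0, doubling_time_h, t, capacity)
        for _ in range(replicates):
            s = alpha * n * _noise(rng, noise_cv)
            times.append(t)
            signals.append(s)
    return np.asarray(times), np.asarray(signals)


def simulate_variance_dataset(
    shares: dict[str, float],
    levels: int = 3,
    replicates: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced full-factorial dataset with planned variance shares.

    Each named factor contributes deterministic, equally spaced, centered
    level effects scaled so its share of total response variance is the
    requested fraction; the remainder (1 - sum of shares) is i.i.d. Gaussian
    noise. Because the design is balanced and orthogonal, a separate one-way
    ANOVA per factor recovers each planned share (up to noise), which is the
    well-posedness check for the variance-component analysis.
    """
    names = list(shares)
    total = sum(shares.values())
    if total >= 1.0 or any(v < 0 for v in shares.values()):
        raise ValidationError("shares must be nonnegative and sum to < 1")
    noise_var = 1.0 - total
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x616e6f76]))

    grids = np.meshgrid(*[np.arange(levels)] * len(names), indexing="ij")
    cells = np.stack([g.ravel() for g in grids], axis=1)
    cells = np.repeat(cells, replicates, axis=0)

    base = np.arange(levels, dtype=float)
    base -= base.mean()
    base_var = float(np.mean(base ** 2))

    y = np.zeros(len(cells))
    data = {}
    for j, name in enumerate(names):
        eff = base * np.sqrt(shares[name] / base_var)
        y += eff[cells[:, j]]
        data[name] = np.array([f"{name}_{k}" for k in cells[:, j]])
    y += rng.normal(0.0, np.sqrt(noise_var), size=len(y))
    data["viability_pct"] = y
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# persistence

def write_simulated(sim: SimulatedScreen, screen_path, truth_path) -> None:
    """Write the screen CSV (plate-table dialect) and the truth YAML sidecar."""
    import yaml
    from .io import write_screen

    write_screen(sim.screen, screen_path)
    with open(truth_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(sim.truth.to_dict(), fh, sort_keys=False)


def read_truth(truth_path) -> SimTruth:
    import yaml

    with open(truth_path, encoding="utf-8") as fh:
        return SimTruth.from_dict(yaml.safe_load(fh))
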