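"""Seeded generators for every input the screening pipeline consumes.

Each generator plants a known ground truth (4PL parameters, sensitizer
potency shifts, grid interaction mode, stabilized-protein membership,
per-arm growth rates) and emits it alongside the noisy tables so recovery
tests never re-derive truth from data.

Design emulated
---------------
* 384-well plates (rows A–P, columns 1–24) with an unseeded two-well buffer
  ring against evaporation edge effects, 18 fixed vehicle (DMSO) wells in
  the seeded interior, and every compound dosed in triplicate six-point
  1:3 dilution series from 10 µM (minimum 0.04 µM).
* A sensitized screening arm in which every well is co-dosed with a fixed
  sub-maximal concentration of a sensitizer; a planted potency shift k
  divides the drug's EC50 in that arm.
* Checkerboard grids: two drugs each varied over a nine-point 1:3 series
  from 10 µM plus a true 0-µM dose, in triplicate, with an additive,
  supra-additive or sub-additive planted combination surface.
* Differential-abundance tables (proteins with per-line log2FC and BH
  q-values, genes with per-line log2FC), a GMT pathway file, and a planted
  stabilized-protein set for the nomination cascade.
* Caliper measurements from per-animal exponential tumour growth,
  log2 volume = beta0 + beta1 * t, with L = W back-computed so the
  ellipsoid volume formula reproduces the target volume.

Measurement noise is multiplicative lognormal with a configurable
coefficient of variation, applied to raw intensities and tumour volumes;
the lognormal is mean-one so noise never biases the expected signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._exceptions import ConfigError, DesignError
from .doseresponse import DoseResponseCurve, dose_for_effect, ll4

__all__ = [
    "DrugSpec",
    "OmicsSpec",
    "TumourSpec",
    "SimulationConfig",
    "generate_dilution_series",
    "simulate_screen",
    "simulate_grid",
    "simulate_omics",
    "simulate_tumours",
    "plate_layout",
    "PLATE_ROWS",
    "PLATE_COLS",
    "BUFFER_ROWS",
    "BUFFER_COLS",
    "VEHICLE_WELLS",
    "PLATE_DRUG_CAPACITY",
]

# ---------------------------------------------------------------------------
# 384-well geometry

PLATE_ROWS: tuple[str, ...] = tuple("ABCDEFGHIJKLMNOP")
PLATE_COLS: tuple[int, ...] = tuple(range(1, 25))
BUFFER_ROWS = frozenset({"A", "B", "O", "P"})
BUFFER_COLS = frozenset({1, 2, 23, 24})

_INTERIOR_ROWS = tuple(r for r in PLATE_ROWS if r not in BUFFER_ROWS)  # C..N
_INTERIOR_COLS = tuple(c for c in PLATE_COLS if c not in BUFFER_COLS)  # 3..22

# 18 fixed vehicle positions scattered over the 12x20 seeded interior.
VEHICLE_WELLS: tuple[tuple[str, int], ...] = tuple(
    (_INTERIOR_ROWS[i % 12], 3 + (7 * i) % 20) for i in range(18)
)

_TREATED_WELLS: tuple[tuple[str, int], ...] = tuple(
    (r, c)
    for r in _INTERIOR_ROWS
    for c in _INTERIOR_COLS
    if (r, c) not in set(VEHICLE_WELLS)
)

#: wells per compound per arm: 6 doses x 3 replicates
_WELLS_PER_DRUG = 18
PLATE_DRUG_CAPACITY = len(_TREATED_WELLS) // _WELLS_PER_DRUG  # 12


def plate_layout() -> dict:
    """Geometry summary of the generated 384-well plates."""
    return {
        "rows": PLATE_ROWS,
        "cols": PLATE_COLS,
        "buffer_rows": sorted(BUFFER_ROWS),
        "buffer_cols": sorted(BUFFER_COLS),
        "vehicle_wells": VEHICLE_WELLS,
        "drug_capacity": PLATE_DRUG_CAPACITY,
    }


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class DrugSpec:
    """Planted single-agent LL.4 curve for one library compound."""

    name: str
    ec50_uM: float
    slope: float = 1.0
    floor: float = 0.0
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        if not self.ec50_uM > 0:
            raise ConfigError(f"{self.name}: planted EC50 must be > 0")
        if self.ceiling < self.floor:
            raise ConfigError(f"{self.name}: ceiling below floor")

    def curve(self, potency_shift: float = 1.0) -> DoseResponseCurve:
        """The planted curve, optionally potency-shifted (EC50 / shift)."""
        return DoseResponseCurve(
            b=self.slope, c=self.floor, d=self.ceiling,
            e=self.ec50_uM / potency_shift, rss=0.0, n_obs=0, converged=True,
        )


@dataclass(frozen=True)
class OmicsSpec:
    """Shape and planted effects of the multi-omic tables.

    ``n_stabilized`` proteins are planted as stabilized (log2FC > 0 with
    q < .05 in both proteome lines, gene log2FC < 0.5 in all transcriptome
    lines); ``n_in_pathway`` of them are additionally placed in the pathway
    union, so they are the ground-truth nomination set.
    """

    n_proteins: int = 500
    n_genes: int = 2000
    n_stabilized: int = 12
    n_in_pathway: int = 5
    protein_lines: tuple[str, ...] = ("A1336", "A2780")
    gene_lines: tuple[str, ...] = ("A1336", "A2780", "SKOV3")
    effect_log2fc: float = 1.5
    null_log2fc_sd: float = 0.3
    gene_null_sd: float = 0.35
    n_pathways: int = 5
    pathway_size: int = 40

    def __post_init__(self) -> None:
        if self.n_stabilized > self.n_proteins:
            raise ConfigError("stabilized set larger than the protein table")
        if self.n_in_pathway > self.n_stabilized:
            raise ConfigError("in-pathway set larger than the stabilized set")
        if self.n_in_pathway > self.n_pathways * self.pathway_size:
            raise ConfigError("stabilized set larger than the pathway capacity")
        if self.n_proteins > self.n_genes:
            raise ConfigError("every protein needs a gene: n_genes < n_proteins")


@dataclass(frozen=True)
class TumourSpec:
    """Per-arm exponential growth: log2 volume = beta0 + beta1 * t.

    Defaults emulate a short xenograft trial: subcutaneous tumours enrolled
    at ~0.65 cm diameter (~144 mm^3, beta0 = log2(144) ≈ 7.17), five animals
    per arm, calipered every 2–3 days over two weeks.  beta1 is in log2 mm^3
    per day, so 1.0 means daily volume doubling.
    """

    arms: dict = field(
        default_factory=lambda: {"vehicle": 0.28, "cisplatin": 0.25, "treated": 0.10}
    )
    beta0: float = 7.17
    animal_beta0_sd: float = 0.15
    days: tuple[float, ...] = (0, 2, 4, 7, 9, 11, 14)
    animals_per_arm: int = 5

    def __post_init__(self) -> None:
        if self.animals_per_arm < 1:
            raise ConfigError("animals_per_arm must be >= 1")
        if any(t < 0 for t in self.days):
            raise ConfigError("measurement days must be non-negative")
        if list(self.days) != sorted(self.days):
            raise ConfigError("measurement days must be sorted ascending")


def default_drug_panel() -> tuple[DrugSpec, ...]:
    """A 12-compound library spanning realistic potencies (one plate per arm).

    EC50s are log-spaced from sub-µM to inactive-at-10-µM, slopes near 1,
    floors between full kill and partial response.
    """
    ec50s = np.round(np.logspace(np.log10(0.3), np.log10(30.0), 12), 3)
    slopes = [1.0, 1.5, 0.8, 1.2, 2.0, 1.0, 1.3, 0.9, 1.1, 1.6, 1.0, 1.4]
    floors = [0.0, 0.05, 0.1, 0.0, 0.2, 0.05, 0.0, 0.15, 0.1, 0.0, 0.25, 0.05]
    return tuple(
        DrugSpec(name=f"cmpd{i + 1:02d}", ec50_uM=float(ec50s[i]),
                 slope=slopes[i], floor=floors[i], ceiling=1.0)
        for i in range(12)
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for all generators; one seed drives everything.

    ``sensitizer_effect`` maps drug name -> multiplicative potency shift
    under co-dosing (EC50 divided by the shift in the sensitized arm);
    drugs not listed shift by 1 (no cooperativity).  The default panel
    plants a single cooperative partner (cmpd04, shift x3) among eleven
    unshifted compounds across seven ovarian cell lines.
    """

    seed: int = 0
    cell_lines: tuple[str, ...] = (
        "COV362", "COV434", "A1336", "IGROV1", "SKOV3", "OVCAR8", "A2780",
    )
    drugs: tuple[DrugSpec, ...] = field(default_factory=default_drug_panel)
    sensitizer_effect: dict = field(default_factory=lambda: {"cmpd04": 3.0})
    noise_cv: float = 0.05
    grid_interaction: str = "additive"
    grid_strength: float = 1.0
    vehicle_baseline: float = 10_000.0
    max_dose_uM: float = 10.0
    n_doses: int = 6
    dilution_ratio: float = 3.0
    omics: OmicsSpec = field(default_factory=OmicsSpec)
    tumour: TumourSpec = field(default_factory=TumourSpec)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if any(s <= 0 for s in self.sensitizer_effect.values()):
            raise ConfigError("sensitizer_effect values must be > 0")
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate drug names in the panel")
        unknown = set(self.sensitizer_effect) - set(names)
        if unknown:
            raise ConfigError(f"sensitizer_effect names unknown drugs: {sorted(unknown)}")
        if self.grid_interaction not in ("additive", "supra", "sub"):
            raise ConfigError(f"unknown grid_interaction {self.grid_interaction!r}")
        if self.grid_interaction == "supra" and not self.grid_strength > 1:
            raise ConfigError("supra-additive interaction needs strength > 1")
        if self.grid_interaction == "sub" and not 0 < self.grid_strength < 1:
            raise ConfigError("sub-additive interaction needs strength in (0, 1)")
        if self.grid_interaction == "additive" and self.grid_strength != 1.0:
            raise ConfigError("additive interaction fixes strength at 1")

    def drug(self, name: str) -> DrugSpec:
        for d in self.drugs:
            if d.name == name:
                return d
        raise ConfigError(f"no drug named {name!r} in the panel")


# ---------------------------------------------------------------------------
# Dilution design

def generate_dilution_series(
    max_dose: float, n_points: int, ratio: float = 3.0
) -> np.ndarray:
    """Descending geometric dilution series starting at ``max_dose`` µM.

    The canonical screening designs are the six-point 1:3 series from 10 µM
    (minimum 0.04 µM) and the nine-point 1:3 series (minimum 0.0015 µM).
    """
    if not max_dose > 0:
        raise DesignError(f"max_dose must be > 0, got {max_dose}")
    if n_points < 2:
        raise DesignError(f"need at least 2 dilution points, got {n_points}")
    if not ratio > 1:
        raise DesignError(f"dilution ratio must be > 1, got {ratio}")
    return max_dose / ratio ** np.arange(n_points, dtype=float)


# ---------------------------------------------------------------------------
# Noise helper

def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


# ---------------------------------------------------------------------------
# Single-agent / sensitized screen

_SCREEN_COLUMNS = [
    "plate_id", "row", "col", "cell_line", "compound", "dose_uM",
    "arm", "replicate", "raw_intensity", "role",
]


def simulate_screen(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Generate the full two-arm viability screen as a long plate table.

    Every drug is dosed in triplicate six-point 1:3 series per arm; each
    plate carries exactly 18 vehicle wells and the unseeded two-well buffer
    ring.  Panels larger than the per-plate capacity split across plates.

    Returns the WellRecord table and a ground-truth dict of planted curves
    per (drug, arm).
    """
    rng = _rng(config, stream=1)
    doses = generate_dilution_series(
        config.max_dose_uM, config.n_doses, config.dilution_ratio
    )
    cap = PLATE_DRUG_CAPACITY
    chunks = [config.drugs[i:i + cap] for i in range(0, len(config.drugs), cap)]

    records: list[tuple] = []
    for cell_line in config.cell_lines:
        for arm in ("single", "sensitized"):
            for p_idx, chunk in enumerate(chunks, start=1):
                plate_id = f"{cell_line}__{arm}__p{p_idx}"
                baseline = config.vehicle_baseline
                # vehicle wells
                for row, col in VEHICLE_WELLS:
                    records.append(
                        (plate_id, row, col, cell_line, "VEHICLE", 0.0,
                         arm, 1, baseline, "vehicle")
                    )
                # treated wells, row-major over the free interior
                cursor = 0
                for drug in chunk:
                    shift = (
                        config.sensitizer_effect.get(drug.name, 1.0)
                        if arm == "sensitized" else 1.0
                    )
                    curve = drug.curve(shift)
                    for dose in doses:
                        viab = ll4(dose, curve.b, curve.c, curve.d, curve.e)
                        for rep in (1, 2, 3):
                            row, col = _TREATED_WELLS[cursor]
                            cursor += 1
                            records.append(
                                (plate_id, row, col, cell_line, drug.name,
                                 float(dose), arm, rep, viab * baseline, "treated")
                            )
                # unused interior wells stay unseeded
                for row, col in _TREATED_WELLS[cursor:]:
                    records.append(
                        (plate_id, row, col, cell_line, "EMPTY", 0.0,
                         arm, 1, 0.02 * baseline, "buffer")
                    )
                # unseeded ring
                for row in PLATE_ROWS:
                    for col in PLATE_COLS:
                        if row in BUFFER_ROWS or col in BUFFER_COLS:
                            records.append(
                                (plate_id, row, col, cell_line, "EMPTY", 0.0,
                                 arm, 1, 0.02 * baseline, "buffer")
                            )

    table = pd.DataFrame.from_records(records, columns=_SCREEN_COLUMNS)
    table["raw_intensity"] *= _lognormal_factors(rng, config.noise_cv, len(table))

    truth = {
        "doses_uM": [float(v) for v in doses],
        "vehicle_baseline": config.vehicle_baseline,
        "noise_cv": config.noise_cv,
        "drugs": {
            d.name: {
                "single": {"b": d.slope, "c": d.floor, "d": d.ceiling, "e": d.ec50_uM},
                "sensitized": {
                    "b": d.slope, "c": d.floor, "d": d.ceiling,
                    "e": d.ec50_uM / config.sensitizer_effect.get(d.name, 1.0),
                },
                "sensitizer_effect": config.sensitizer_effect.get(d.name, 1.0),
            }
            for d in config.drugs
        },
    }
    return table, truth


# ---------------------------------------------------------------------------
# Checkerboard grid

def loewe_additive_effect(
    curve_a: DoseResponseCurve,
    curve_b: DoseResponseCurve,
    a: float,
    b: float,
    strength: float = 1.0,
) -> float:
    """Planted combination viability at doses (a, b) under Loewe dose addition.

    Solves a/A(E) + b/B(E) = 1/strength for the effect E, where A(E), B(E)
    invert the single-agent curves.  strength 1 is exactly Loewe-additive
    (so the measured combination index is 1 everywhere); strength k scales
    the effective dose, giving CI = 1/k (< 1 supra-additive, > 1 sub-).
    For identical agents this reduces to the closed form f((a + b) * k).
    """
    if a == 0 and b == 0:
        return float(min(curve_a.d, curve_b.d))
    if b == 0:
        return float(ll4(a, curve_a.b, curve_a.c, curve_a.d, curve_a.e))
    if a == 0:
        return float(ll4(b, curve_b.b, curve_b.c, curve_b.d, curve_b.e))

    same = (
        curve_a.b == curve_b.b and curve_a.c == curve_b.c
        and curve_a.d == curve_b.d and curve_a.e == curve_b.e
    )
    if same:
        return float(ll4((a + b) * strength, curve_a.b, curve_a.c, curve_a.d, curve_a.e))

    from scipy.optimize import brentq

    lo = max(curve_a.c, curve_b.c)
    hi = min(curve_a.d, curve_b.d)
    span = hi - lo
    if span <= 0:
        raise ConfigError("margin curves share no attainable effect range")

    def g(effect: float) -> float:
        da = dose_for_effect(curve_a, effect)
        db = dose_for_effect(curve_b, effect)
        return a / da + b / db - 1.0 / strength

    eps = 1e-9 * span
    # g decreases in effect: near the shared ceiling doses ~0 so g > 0.
    # If g is still positive at the shared floor the combination saturates
    # there (the dose-equivalent sum exceeds what the weaker margin can
    # express); clamp rather than extrapolate past an asymptote.
    if g(lo + eps) > 0:
        return float(lo + eps)
    return float(brentq(g, lo + eps, hi - eps, xtol=1e-12, rtol=1e-14))


_GRID_COLUMNS = [
    "cell_line", "drug_a", "drug_b", "dose_a_uM", "dose_b_uM",
    "replicate", "raw_intensity", "role",
]


def simulate_grid(
    config: SimulationConfig,
    drug_a: str,
    drug_b: str,
    cell_line: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a triplicate 10x10 checkerboard (nine-point 1:3 series + 0 µM).

    The planted surface follows ``config.grid_interaction`` /
    ``config.grid_strength``; the zero-dose margins are exact single-agent
    responses, and the (0, 0) cell is the vehicle reference.
    """
    rng = _rng(config, stream=2)
    spec_a, spec_b = config.drug(drug_a), config.drug(drug_b)
    curve_a, curve_b = spec_a.curve(), spec_b.curve()
    cell_line = cell_line or config.cell_lines[0]

    series = generate_dilution_series(config.max_dose_uM, 9, config.dilution_ratio)
    doses = np.concatenate(([0.0], series[::-1]))  # ascending, 0 first

    records = []
    surface = {}
    for da in doses:
        for db in doses:
            viab = loewe_additive_effect(
                curve_a, curve_b, float(da), float(db), config.grid_strength
            )
            surface[(float(da), float(db))] = viab
            for rep in (1, 2, 3):
                records.append(
                    (cell_line, drug_a, drug_b, float(da), float(db), rep,
                     viab * config.vehicle_baseline,
                     "vehicle" if da == 0 and db == 0 else "treated")
                )
    table = pd.DataFrame.from_records(records, columns=_GRID_COLUMNS)
    table["raw_intensity"] *= _lognormal_factors(rng, config.noise_cv, len(table))

    truth = {
        "drug_a": drug_a,
        "drug_b": drug_b,
        "interaction": config.grid_interaction,
        "strength": config.grid_strength,
        "curves": {
            drug_a: {"b": spec_a.slope, "c": spec_a.floor, "d": spec_a.ceiling, "e": spec_a.ec50_uM},
            drug_b: {"b": spec_b.slope, "c": spec_b.floor, "d": spec_b.ceiling, "e": spec_b.ec50_uM},
        },
        "surface": {f"{k[0]}|{k[1]}": v for k, v in surface.items()},
    }
    return table, truth


# ---------------------------------------------------------------------------
# Multi-omic tables

def simulate_omics(config: SimulationConfig) -> dict:
    """Generate protein/gene differential tables, pathways and ground truth.

    Returns a dict with keys ``proteins`` (DataFrame: protein_id, gene_id,
    log2fc_<line>, q_<line>), ``genes`` (gene_id, log2fc_<line>),
    ``pathways`` (name -> gene list) and ``truth`` (planted memberships).
    q-values are Benjamini–Hochberg adjustments of simulated p-values,
    computed per cell line over the whole protein table.
    """
    spec = config.omics
    rng = _rng(config, stream=3)

    gene_ids = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    protein_ids = [f"P{i + 1:05d}" for i in range(spec.n_proteins)]
    # protein i maps to gene i
    mapping = dict(zip(protein_ids, gene_ids[: spec.n_proteins]))

    stab_idx = rng.choice(spec.n_proteins, size=spec.n_stabilized, replace=False)
    stabilized = [protein_ids[i] for i in sorted(stab_idx)]
    in_pathway = stabilized[: spec.n_in_pathway]
    out_pathway = stabilized[spec.n_in_pathway:]
    stab_set = set(stabilized)

    proteins = pd.DataFrame({"protein_id": protein_ids,
                             "gene_id": [mapping[p] for p in protein_ids]})
    for line in spec.protein_lines:
        lfc = rng.normal(0.0, spec.null_log2fc_sd, spec.n_proteins)
        pvals = rng.uniform(0.0, 1.0, spec.n_proteins)
        for i, pid in enumerate(protein_ids):
            if pid in stab_set:
                lfc[i] = spec.effect_log2fc * rng.uniform(0.8, 1.2)
                pvals[i] = rng.uniform(1e-10, 1e-7)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        proteins[f"log2fc_{line}"] = lfc
        proteins[f"q_{line}"] = qvals

    stab_genes = {mapping[p] for p in stabilized}
    genes = pd.DataFrame({"gene_id": gene_ids})
    for line in spec.gene_lines:
        lfc = rng.normal(0.0, spec.gene_null_sd, spec.n_genes)
        for i, gid in enumerate(gene_ids):
            if gid in stab_genes:
                # stabilized at the protein level but not transcriptionally up
                lfc[i] = rng.uniform(-0.2, 0.3)
        genes[f"log2fc_{line}"] = lfc

    # pathways: planted in-pathway genes live in the first set; the
    # out-of-pathway stabilized genes are excluded from every set
    excluded = {mapping[p] for p in out_pathway}
    pool = [g for g in gene_ids if g not in excluded and g not in
            {mapping[p] for p in in_pathway}]
    pathways: dict[str, list[str]] = {}
    pool_idx = rng.permutation(len(pool))
    cursor = 0
    planted_genes = [mapping[p] for p in in_pathway]
    for k in range(spec.n_pathways):
        n_fill = spec.pathway_size - (len(planted_genes) if k == 0 else 0)
        members = [pool[i] for i in pool_idx[cursor:cursor + n_fill]]
        cursor += n_fill
        if k == 0:
            members = planted_genes + members
        pathways[f"pathway_{k + 1:02d}"] = members

    truth = {
        "stabilized": stabilized,
        "stabilized_in_pathway": in_pathway,
        "stabilized_genes": sorted(stab_genes),
        "mapping": mapping,
    }
    return {"proteins": proteins, "genes": genes, "pathways": pathways, "truth": truth}


# ---------------------------------------------------------------------------
# Tumour growth

def simulate_tumours(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Generate caliper tables from per-animal exponential growth.

    Volume at day t is 2**(beta0_i + beta1_arm * t) times mean-one lognormal
    noise (CV = ``config.noise_cv``); the two perpendicular diameters are
    back-computed under L = W so the ellipsoid volume formula reproduces the
    simulated volume exactly.
    """
    spec = config.tumour
    rng = _rng(config, stream=4)

    rows = []
    truth_animals = {}
    for arm, beta1 in spec.arms.items():
        for k in range(spec.animals_per_arm):
            animal = f"{arm}_{k + 1:02d}"
            beta0_i = spec.beta0 + rng.normal(0.0, spec.animal_beta0_sd)
            truth_animals[animal] = {"arm": arm, "beta0": float(beta0_i),
                                     "beta1": float(beta1)}
            noise = _lognormal_factors(rng, config.noise_cv, len(spec.days))
            for t, nz in zip(spec.days, noise):
                volume = 2.0 ** (beta0_i + beta1 * t) * nz
                # invert the ellipsoid formula at L = W:
                # V = (pi/6) * L^3 * 1e3  (L in cm, V in mm^3)
                L = (volume / (np.pi / 6.0 * 1e3)) ** (1.0 / 3.0)
                rows.append((animal, arm, float(t), float(L), float(L)))
    table = pd.DataFrame(rows, columns=["animal", "arm", "day", "L_cm", "W_cm"])
    truth = {"arms": dict(spec.arms), "animals": truth_animals,
             "noise_cv": config.noise_cv}
    return table, truth


# ---------------------------------------------------------------------------
# Sidecar output

def write_ground_truth(truth: dict, path: str | Path) -> None:
    """Write a planted-truth sidecar as JSON."""
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
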