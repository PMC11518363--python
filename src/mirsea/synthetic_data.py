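"""Synthetic two-condition qPCR miRNome panel data with known ground truth.

Emulates a 384-well miRNome profiling panel: 372 miRNA assays, three
interplate calibrators, three reference-gene assays, five RNA spike-in
controls and one blank well. Raw signal is a per-well amplification curve
(fluorescence over PCR cycles) modelled as a four-parameter logistic; the
curve midpoint is placed so that the second-derivative-maximum cycle equals
the prescribed true Cq, which gives every downstream stage an exact oracle.

Differential expression is planted at the Cq level: an up-regulated miRNA in
condition 2 has its condition-2 true Cq lowered by the effect size delta
(one Cq cycle = one doubling on the 2^-dCq scale). Reference genes,
calibrators and spike-ins are condition-invariant by construction; blank
wells produce flat, non-amplifying traces. A per-sample plate offset (every
sample runs on its own panel plate) is added to all Cq on that plate and is
what interplate calibration must remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .set_collections import normalize_mirna_name

WELL_CLASSES = (
    "mirna_assay",
    "interplate_calibrator",
    "reference_gene",
    "spike_in",
    "blank",
)
WellClass = Literal[
    "mirna_assay", "interplate_calibrator", "reference_gene", "spike_in", "blank"
]

DEFAULT_CLASS_COUNTS = {
    "mirna_assay": 372,
    "interplate_calibrator": 3,
    "reference_gene": 3,
    "spike_in": 5,
    "blank": 1,
}

#: For a logistic rise f(c) = baseline + f_max / (1 + exp(-k (c - m))), the
#: maximum of the second derivative sits at c = m - ln(2 + sqrt(3)) / k.
SDM_OFFSET = math.log(2.0 + math.sqrt(3.0))

CONDITION_NAMES = ("WWOX_deficient", "WWOX_sufficient")


@dataclass(frozen=True)
class Well:
    well_id: str
    assay_name: str
    well_class: str


@dataclass
class PanelLayout:
    """A plate layout: ordered wells with assay names and well classes."""

    wells: list[Well]
    plate_id: str = "panel"

    def __post_init__(self) -> None:
        names = [w.assay_name for w in self.wells if w.well_class != "blank"]
        if len(names) != len(set(names)):
            raise ValueError("assay names must be unique per plate")
        for w in self.wells:
            if w.well_class not in WELL_CLASSES:
                raise ValueError(f"unknown well class {w.well_class!r}")
            if w.well_class == "blank" and w.assay_name:
                raise ValueError("blank wells have no assay target")

    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in WELL_CLASSES}
        for w in self.wells:
            out[w.well_class] += 1
        return out

    def assays_of_class(self, well_class: str) -> list[str]:
        return [w.assay_name for w in self.wells if w.well_class == well_class]

    @property
    def mirna_assays(self) -> list[str]:
        return self.assays_of_class("mirna_assay")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well_id": [w.well_id for w in self.wells],
                "assay_name": [w.assay_name for w in self.wells],
                "well_class": [w.well_class for w in self.wells],
            }
        )


def load_panel_mirna_names() -> list[str]:
    """The packaged list of 372 human miRNA assay names."""
    text = resources.files("mirsea.data").joinpath("mirna_panel_names.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


# Control assay names in the style of commercial LNA miRNome panels.
_CALIBRATORS = ("UniSp3-IPC-1", "UniSp3-IPC-2", "UniSp3-IPC-3")
_REFERENCE_GENES = ("SNORD38B", "SNORD49A", "U6-snRNA")
_SPIKE_INS = ("UniSp2", "UniSp4", "UniSp5", "UniSp6", "cel-miR-39-3p")


def make_default_layout() -> PanelLayout:
    """The default 384-well panel: 372 miRNA / 3 calibrator / 3 reference /
    5 spike-in / 1 blank wells."""
    mirnas = load_panel_mirna_names()
    if len(mirnas) != DEFAULT_CLASS_COUNTS["mirna_assay"]:
        raise RuntimeError("packaged miRNA name list does not have 372 entries")
    assays: list[tuple[str, str]] = [(m, "mirna_assay") for m in mirnas]
    assays += [(a, "interplate_calibrator") for a in _CALIBRATORS]
    assays += [(a, "reference_gene") for a in _REFERENCE_GENES]
    assays += [(a, "spike_in") for a in _SPIKE_INS]
    assays += [("", "blank")]
    rows = "ABCDEFGHIJKLMNOP"
    well_ids = [f"{r}{c}" for r in rows for c in range(1, 25)]
    wells = [Well(w, a, k) for w, (a, k) in zip(well_ids, assays)]
    return PanelLayout(wells=wells, plate_id="panel-384")


@dataclass(frozen=True)
class CurveParams:
    """Four-parameter-logistic amplification curve parameters.

    f_max: plateau fluorescence rise above baseline (arbitrary units).
    slope: logistic growth rate k per cycle.
    baseline: pre-amplification fluorescence level.
    noise_sd: SD of additive i.i.d. Gaussian noise on fluorescence.
    """

    f_max: float = 10.0
    slope: float = 1.0
    baseline: float = 0.5
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not (self.f_max > 0 and self.slope > 0):
            raise ValueError("f_max and slope must be positive")
        if not (self.noise_sd >= 0 and np.isfinite(self.noise_sd)):
            raise ValueError("noise_sd must be finite and non-negative")


@dataclass(frozen=True)
class AmplificationCurve:
    """A per-well fluorescence trace over PCR cycles."""

    well_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cycles)
        f = np.asarray(self.fluorescence)
        if c.size < 10:
            raise ValueError("need at least 10 cycles")
        if not np.all(np.diff(c) > 0):
            raise ValueError("cycles must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise ValueError("fluorescence must be finite")
        object.__setattr__(self, "cycles", c.astype(float))
        object.__setattr__(self, "fluorescence", f.astype(float))


def logistic_curve(cycles: np.ndarray, true_cq: float, params: CurveParams) -> np.ndarray:
    """Noiseless logistic fluorescence with its SDM cycle at ``true_cq``."""
    m = true_cq + SDM_OFFSET / params.slope
    return params.baseline + params.f_max / (
        1.0 + np.exp(-params.slope * (np.asarray(cycles, dtype=float) - m))
    )


def simulate_curve(
    true_cq: float,
    params: CurveParams,
    rng: np.random.Generator,
    n_cycles: int = 45,
    well_id: str = "",
) -> AmplificationCurve:
    """Simulate one amplification curve whose SDM Cq equals ``true_cq``."""
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    if not (cycles[0] <= true_cq <= cycles[-1]):
        raise ValueError(f"true_cq={true_cq} outside cycle range [1, {n_cycles}]")
    f = logistic_curve(cycles, true_cq, params)
    if params.noise_sd > 0:
        f = f + rng.normal(0.0, params.noise_sd, size=cycles.size)
    return AmplificationCurve(well_id=well_id, cycles=cycles, fluorescence=f)


@dataclass(frozen=True)
class PlantedSet:
    """A coherently shifted miRNA set: all members move in one direction."""

    name: str
    members: tuple[str, ...]
    direction: Literal["up", "down"] = "up"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        object.__setattr__(
            self, "members", tuple(normalize_mirna_name(m) for m in self.members)
        )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-condition panel experiment.

    Direction convention follows qPCR semantics: 'up' means up-regulated in
    condition 2 relative to condition 1, i.e. condition-2 Cq lowered by
    ``de_effect_size`` cycles.
    """

    n_samples_per_condition: int = 3
    n_de_mirnas: int = 20
    de_effect_size: float = 2.0
    curve_params: CurveParams = field(default_factory=CurveParams)
    planted_sets: tuple[PlantedSet, ...] = ()
    seed: int = 0
    n_cycles: int = 45
    condition_names: tuple[str, str] = CONDITION_NAMES
    interplate_offset_sd: float = 0.3
    base_cq_mean: float = 25.0
    base_cq_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.n_samples_per_condition < 1:
            raise ValueError("n_samples_per_condition must be >= 1")
        if self.n_de_mirnas < 0:
            raise ValueError("n_de_mirnas must be >= 0")
        if not (self.de_effect_size > 0 and np.isfinite(self.de_effect_size)):
            raise ValueError("de_effect_size must be a positive finite real")
        if len(set(self.condition_names)) != 2:
            raise ValueError("need two distinct condition names")


@dataclass
class SimulatedExperiment:
    """Simulator output: raw curves plus the planted ground truth."""

    layout: PanelLayout
    config: SimulationConfig
    curves: pd.DataFrame  # long: plate_id, well_id, sample_id, assay_name, well_class, cycle, fluorescence
    true_cq: pd.DataFrame  # sample_id, plate_id, assay_name, well_class, true_cq (NaN for blanks)
    ground_truth: pd.DataFrame  # mirna, direction, source
    conditions: pd.Series  # sample_id -> condition label

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "curves": out / "curves.tsv",
            "layout": out / "layout.tsv",
            "ground_truth": out / "ground_truth.tsv",
            "conditions": out / "conditions.tsv",
        }
        self.curves.to_csv(paths["curves"], sep="\t", index=False, float_format="%.6g")
        self.layout.to_frame().to_csv(paths["layout"], sep="\t", index=False)
        self.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
        self.conditions.rename("condition").rename_axis("sample_id").to_csv(
            paths["conditions"], sep="\t"
        )
        return paths


def _planted_shift_directions(config: SimulationConfig) -> dict[str, str]:
    """Per-miRNA direction from planted sets; conflicting directions error."""
    directions: dict[str, str] = {}
    for ps in config.planted_sets:
        for m in ps.members:
            prev = directions.get(m)
            if prev is not None and prev != ps.direction:
                raise ValueError(
                    f"planted member {m!r} has conflicting directions "
                    f"({prev!r} vs {ps.direction!r} in set {ps.name!r})"
                )
            directions[m] = ps.direction
    return directions


def simulate_experiment(
    layout: PanelLayout, config: SimulationConfig
) -> SimulatedExperiment:
    """Simulate curves for every sample and well, with planted differentials.

    Deterministic for a fixed config (all randomness flows from one seeded
    generator). Raises a configuration error when a planted-set member is not
    a miRNA assay on the layout.
    """
    rng = np.random.default_rng(config.seed)
    mirnas = layout.mirna_assays
    mirna_set = set(mirnas)

    planted_dirs = _planted_shift_directions(config)
    missing = sorted(set(planted_dirs) - mirna_set)
    if missing:
        raise ValueError(f"planted members absent from layout: {missing}")

    # Per-assay baseline Cq, shared across samples and conditions.
    base_cq: dict[str, float] = {}
    for m in mirnas:
        base_cq[m] = float(
            np.clip(
                rng.normal(config.base_cq_mean, config.base_cq_sd),
                20.0,
                config.n_cycles - 12.0,
            )
        )
    for a in layout.assays_of_class("reference_gene"):
        base_cq[a] = float(rng.normal(19.0, 0.3))
    for a in layout.assays_of_class("spike_in"):
        base_cq[a] = float(rng.normal(21.0, 0.3))
    for a in layout.assays_of_class("interplate_calibrator"):
        base_cq[a] = 20.0

    # Randomly differential miRNAs, disjoint from planted-set members.
    eligible = [m for m in mirnas if m not in planted_dirs]
    if config.n_de_mirnas > len(eligible):
        raise ValueError("n_de_mirnas exceeds the number of eligible miRNA assays")
    de_pick = list(rng.choice(eligible, size=config.n_de_mirnas, replace=False))
    de_dirs = {m: ("up" if rng.random() < 0.5 else "down") for m in de_pick}

    gt_rows = [
        {"mirna": m, "direction": d, "source": "random_de"} for m, d in de_dirs.items()
    ]
    for ps in config.planted_sets:
        gt_rows += [
            {"mirna": m, "direction": ps.direction, "source": ps.name}
            for m in ps.members
        ]
    ground_truth = pd.DataFrame(gt_rows, columns=["mirna", "direction", "source"])

    shift = {**de_dirs, **planted_dirs}
    delta = config.de_effect_size
    cond2 = config.condition_names[1]

    cycles = np.arange(1, config.n_cycles + 1, dtype=float)
    sample_ids: list[str] = []
    cond_of: dict[str, str] = {}
    for cond in config.condition_names:
        for i in range(config.n_samples_per_condition):
            sid = f"{cond}_{i + 1}"
            sample_ids.append(sid)
            cond_of[sid] = cond

    curve_blocks: list[np.ndarray] = []
    meta_rows: list[tuple[str, str, str, str, str, float]] = []
    for sid in sample_ids:
        plate_id = f"plate_{sid}"
        plate_offset = float(rng.normal(0.0, config.interplate_offset_sd))
        for w in layout.wells:
            if w.well_class == "blank":
                tcq = math.nan
                f = np.full(cycles.size, config.curve_params.baseline)
            else:
                tcq = base_cq[w.assay_name] + plate_offset
                if cond_of[sid] == cond2 and w.assay_name in shift:
                    # up-regulated in condition 2 -> lower Cq there
                    tcq += -delta if shift[w.assay_name] == "up" else delta
                f = logistic_curve(cycles, tcq, config.curve_params)
            if config.curve_params.noise_sd > 0:
                f = f + rng.normal(0.0, config.curve_params.noise_sd, size=cycles.size)
            curve_blocks.append(f)
            meta_rows.append((plate_id, w.well_id, sid, w.assay_name, w.well_class, tcq))

    n_wells = len(meta_rows)
    meta = pd.DataFrame(
        meta_rows,
        columns=["plate_id", "well_id", "sample_id", "assay_name", "well_class", "true_cq"],
    )
    curves = meta.drop(columns="true_cq").loc[
        np.repeat(np.arange(n_wells), cycles.size)
    ].reset_index(drop=True)
    curves["cycle"] = np.tile(cycles.astype(int), n_wells)
    curves["fluorescence"] = np.concatenate(curve_blocks)

    conditions = pd.Series(cond_of, name="condition")
    conditions.index.name = "sample_id"
    return SimulatedExperiment(
        layout=layout,
        config=config,
        curves=curves,
        true_cq=meta[["sample_id", "plate_id", "assay_name", "well_class", "true_cq"]],
        ground_truth=ground_truth,
        conditions=conditions,
    )
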