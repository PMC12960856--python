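"""File I/O, factorial sweeps and the synthetic bench generator.

This module ties the package together: it reads catalog CSVs and
YAML/JSON component libraries and circuit configs, runs the factorial
drain x return x rpm x height sweep, and generates seeded synthetic bench
measurements (predictions plus Gaussian noise) for end-to-end validation.

File dialects
-------------
Catalog CSV: header ``flow_l_min,pressure_mmhg``, one file per component
or pump rpm; UTF-8, ``.`` decimal.

Component library (YAML or JSON)::

    components:
      - {name: ..., kind: ..., k1: ..., k2: ..., k3: 0}       # explicit
      - {name: ..., kind: ..., points_file: cannula.csv}      # fitted
      - {name: ..., kind: connecting_tube, length_m: 0.5}     # default tube
    pumps:
      - name: ...
        curves: {3000: {k1: ..., k2: ..., k3: ...}, 3500: points.csv}

Circuit config (YAML or JSON): ``drainage_side``, ``pump``, ``rpm``,
``return_side``, ``cvp_mmhg``, ``bed_height_cm``; component references
resolve against a library.

Measurement CSV: header ``combo_id,drain_fr,return_fr,rpm,bed_height_cm,
q_meas_l_min,p1_mmhg,p2_mmhg,p3_mmhg``.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .circuit_solver import CircuitDefinition, predict_circuit
from .component_model import (
    CatalogPointSet,
    PassiveComponent,
    PumpModel,
    QuadraticCurve,
    connecting_tube,
    fit_quadratic_curve,
)
from .errors import EcmoflowError, LibraryError
from .validation_stats import PairedSeries, ValidationReport, compute_validation_stats

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "combo_id", "drain_fr", "return_fr", "rpm", "bed_height_cm",
    "q_meas_l_min", "p1_mmhg", "p2_mmhg", "p3_mmhg",
]

PREDICTION_COLUMNS = [
    "combo_id", "drain", "return", "rpm", "bed_height_cm",
    "q_l_min", "p1_mmhg", "p2_mmhg", "p3_mmhg", "error",
]


@dataclass(frozen=True)
class ComponentLibrary:
    """Named passive components and pumps loaded from a library file."""

    components: Mapping[str, PassiveComponent]
    pumps: Mapping[str, PumpModel]

    def component(self, name: str) -> PassiveComponent:
        try:
            return self.components[name]
        except KeyError:
            raise LibraryError(
                f"unknown component {name!r}; available: "
                f"{sorted(self.components)}"
            ) from None

    def pump(self, name: str) -> PumpModel:
        try:
            return self.pumps[name]
        except KeyError:
            raise LibraryError(
                f"unknown pump {name!r}; available: {sorted(self.pumps)}"
            ) from None


def read_catalog_csv(path: str | Path, source_label: str = "") -> CatalogPointSet:
    """Read a ``flow_l_min,pressure_mmhg`` catalog CSV into a point set."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"flow_l_min", "pressure_mmhg"} - set(df.columns)
    if missing:
        raise LibraryError(
            f"{path}: catalog CSV missing column(s) {sorted(missing)}"
        )
    return CatalogPointSet(
        points=tuple(zip(df["flow_l_min"], df["pressure_mmhg"])),
        source_label=source_label or path.stem,
    )


def _load_mapping(path: Path) -> dict:
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as e:
        raise LibraryError(f"{path}: cannot parse: {e}") from e
    if not isinstance(data, dict):
        raise LibraryError(f"{path}: expected a mapping at top level")
    return data


def _curve_from_entry(entry: dict, base_dir: Path, label: str,
                      constrain: bool) -> QuadraticCurve:
    if "points_file" in entry:
        pts = read_catalog_csv(base_dir / entry["points_file"], source_label=label)
        return fit_quadratic_curve(pts, constrain_zero_intercept=constrain)
    try:
        return QuadraticCurve(
            float(entry["k1"]), float(entry["k2"]), float(entry.get("k3", 0.0))
        )
    except KeyError as e:
        raise LibraryError(
            f"{label}: entry needs either points_file or explicit k1/k2 "
            f"(missing {e})"
        ) from None


def load_component_library(path: str | Path) -> ComponentLibrary:
    """Load and validate a YAML/JSON component library.

    Point-file entries are fitted on load with the component kind's
    intercept constraint (zero for passives, free for pumps); every type
    invariant is checked here so downstream code can trust the objects.
    """
    path = Path(path)
    if not path.exists():
        raise LibraryError(f"library file not found: {path}")
    data = _load_mapping(path)
    base = path.parent

    components: dict[str, PassiveComponent] = {}
    for entry in data.get("components", []):
        try:
            name = entry["name"]
            kind = entry["kind"]
        except (KeyError, TypeError) as e:
            raise LibraryError(f"{path}: component entry missing {e}: {entry}")
        try:
            if (kind == "connecting_tube" and "k1" not in entry
                    and "points_file" not in entry):
                comp = connecting_tube(name, float(entry["length_m"]))
            else:
                curve = _curve_from_entry(entry, base, name, constrain=True)
                comp = PassiveComponent(
                    name=name, kind=kind, curve=curve,
                    size_fr=entry.get("size_fr"),
                    length_m=entry.get("length_m"),
                )
        except EcmoflowError as e:
            raise LibraryError(f"{path}: component {name!r}: {e}") from e
        if name in components:
            raise LibraryError(f"{path}: duplicate component name {name!r}")
        components[name] = comp

    pumps: dict[str, PumpModel] = {}
    for entry in data.get("pumps", []):
        try:
            name = entry["name"]
            curves_spec = entry["curves"]
        except (KeyError, TypeError) as e:
            raise LibraryError(f"{path}: pump entry missing {e}: {entry}")
        curves: dict[int, QuadraticCurve] = {}
        for rpm, spec in curves_spec.items():
            label = f"{name}@{rpm}rpm"
            if isinstance(spec, str):
                pts = read_catalog_csv(base / spec, source_label=label)
                curves[int(rpm)] = fit_quadratic_curve(
                    pts, constrain_zero_intercept=False
                )
            else:
                curves[int(rpm)] = _curve_from_entry(
                    spec, base, label, constrain=False
                )
        try:
            pumps[name] = PumpModel(name=name, curves_by_rpm=curves)
        except EcmoflowError as e:
            raise LibraryError(f"{path}: pump {name!r}: {e}") from e

    if not components and not pumps:
        raise LibraryError(f"{path}: library defines no components or pumps")
    return ComponentLibrary(components=components, pumps=pumps)


def default_library() -> ComponentLibrary:
    """The synthetic component set shipped with the package.

    Sizes and speeds mirror a 2x2 cannula grid at 2500/3000/3500 rpm;
    coefficient values are invented (shape-plausible), not manufacturer
    data.
    """
    ref = importlib.resources.files("ecmoflow.data") / "default_library.yaml"
    with importlib.resources.as_file(ref) as p:
        return load_component_library(p)


def load_circuit_config(
    path: str | Path,
    library: ComponentLibrary,
    rpm: int | None = None,
    cvp: float | None = None,
    bed_height_cm: float | None = None,
) -> CircuitDefinition:
    """Build a :class:`CircuitDefinition` from a config file.

    ``rpm``/``cvp``/``bed_height_cm`` override the file's values (CLI
    flags).
    """
    path = Path(path)
    if not path.exists():
        raise LibraryError(f"circuit config not found: {path}")
    data = _load_mapping(path)
    try:
        drainage = [library.component(n) for n in data["drainage_side"]]
        return_side = [library.component(n) for n in data["return_side"]]
        pump = library.pump(data["pump"])
    except KeyError as e:
        raise LibraryError(f"{path}: circuit config missing key {e}") from None
    return CircuitDefinition(
        drainage_side=tuple(drainage),
        pump=pump,
        rpm=int(rpm if rpm is not None else data["rpm"]),
        return_side=tuple(return_side),
        cvp=float(cvp if cvp is not None else data.get("cvp_mmhg", 0.0)),
        bed_height_cm=float(
            bed_height_cm if bed_height_cm is not None
            else data.get("bed_height_cm", 0.0)
        ),
    )


@dataclass(frozen=True)
class SweepGrid:
    """Factorial grid over cannulas, pump speeds and bed heights.

    The shared plumbing (tube 1, tube 2, oxygenator, tube 3) and the CVP
    are fixed across all combinations; the row order of the sweep is the
    deterministic nested loop drain -> return -> rpm -> height.
    """

    drainage_cannulas: tuple[str, ...]
    return_cannulas: tuple[str, ...]
    rpms: tuple[int, ...]
    bed_heights_cm: tuple[float, ...]
    pump: str = "pump"
    tube1: str = "tube1"
    tube2: str = "tube2"
    oxygenator: str = "oxygenator"
    tube3: str = "tube3"
    cvp_mmhg: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "drainage_cannulas", tuple(self.drainage_cannulas))
        object.__setattr__(self, "return_cannulas", tuple(self.return_cannulas))
        object.__setattr__(self, "rpms", tuple(int(r) for r in self.rpms))
        object.__setattr__(
            self, "bed_heights_cm", tuple(float(h) for h in self.bed_heights_cm)
        )

    def __len__(self) -> int:
        return (len(self.drainage_cannulas) * len(self.return_cannulas)
                * len(self.rpms) * len(self.bed_heights_cm))


#: Grid mirroring the bench protocol: 2 drainage x 2 return cannulas,
#: 3 pump speeds, 3 bed heights = 36 combinations.
DEFAULT_GRID = SweepGrid(
    drainage_cannulas=("drain_18fr", "drain_22fr"),
    return_cannulas=("return_14fr", "return_18fr"),
    rpms=(2500, 3000, 3500),
    bed_heights_cm=(0.0, 40.0, 80.0),
)


def build_circuit(
    grid: SweepGrid, library: ComponentLibrary,
    drain: str, ret: str, rpm: int, height_cm: float,
) -> CircuitDefinition:
    """Assemble one grid combination into a circuit."""
    return CircuitDefinition(
        drainage_side=(library.component(drain), library.component(grid.tube1)),
        pump=library.pump(grid.pump),
        rpm=rpm,
        return_side=(
            library.component(grid.tube2),
            library.component(grid.oxygenator),
            library.component(grid.tube3),
            library.component(ret),
        ),
        cvp=grid.cvp_mmhg,
        bed_height_cm=height_cm,
    )


def _combo_id(drain: str, ret: str, rpm: int, height_cm: float) -> str:
    h = int(height_cm) if float(height_cm).is_integer() else height_cm
    return f"{drain}|{ret}|{rpm}rpm|{h}cm"


def run_sweep(grid: SweepGrid, library: ComponentLibrary) -> pd.DataFrame:
    """Predict flow and P1/P2/P3 for every grid combination.

    Returns one row per combination.  Unsolvable combinations are flagged
    in the ``error`` column (NaN predictions) and the sweep continues;
    callers that need a hard failure should check ``error.notna().any()``.
    """
    rows = []
    for drain in grid.drainage_cannulas:
        for ret in grid.return_cannulas:
            for rpm in grid.rpms:
                for height in grid.bed_heights_cm:
                    circuit = build_circuit(grid, library, drain, ret, rpm, height)
                    row = {
                        "combo_id": _combo_id(drain, ret, rpm, height),
                        "drain": drain, "return": ret, "rpm": rpm,
                        "bed_height_cm": height,
                        "q_l_min": np.nan, "p1_mmhg": np.nan,
                        "p2_mmhg": np.nan, "p3_mmhg": np.nan, "error": None,
                    }
                    try:
                        res = predict_circuit(circuit)
                        row.update(
                            q_l_min=res.q, p1_mmhg=res.p1,
                            p2_mmhg=res.p2, p3_mmhg=res.p3,
                        )
                    except EcmoflowError as e:
                        logger.warning("combo %s failed: %s", row["combo_id"], e)
                        row["error"] = str(e)
                    rows.append(row)
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


@dataclass(frozen=True)
class SyntheticBenchSpec:
    """Recipe for a synthetic bench run: grid + noise levels + seed.

    Measurements are the model's own predictions perturbed by iid Gaussian
    noise (sd_flow on flow, sd_pressure on each tap), emulating transducer
    and flow-probe scatter.  The seed fixes the output byte-for-byte.
    """

    grid: SweepGrid
    sd_flow: float = 0.1
    sd_pressure: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.sd_flow < 0 or self.sd_pressure < 0:
            raise LibraryError("noise standard deviations must be >= 0")


def generate_synthetic_bench(
    spec: SyntheticBenchSpec, library: ComponentLibrary
) -> pd.DataFrame:
    """Measurement table = sweep predictions + seeded Gaussian noise."""
    preds = run_sweep(spec.grid, library)
    if preds["error"].notna().any():
        bad = preds.loc[preds["error"].notna(), "combo_id"].tolist()
        raise EcmoflowError(f"sweep failed for combos: {bad}")
    rng = np.random.default_rng(spec.seed)
    n = len(preds)
    out = pd.DataFrame({
        "combo_id": preds["combo_id"],
        "drain_fr": [library.component(d).size_fr for d in preds["drain"]],
        "return_fr": [library.component(r).size_fr for r in preds["return"]],
        "rpm": preds["rpm"],
        "bed_height_cm": preds["bed_height_cm"],
        "q_meas_l_min": preds["q_l_min"] + rng.normal(0, spec.sd_flow, n)
        if spec.sd_flow > 0 else preds["q_l_min"],
        "p1_mmhg": preds["p1_mmhg"] + rng.normal(0, spec.sd_pressure, n)
        if spec.sd_pressure > 0 else preds["p1_mmhg"],
        "p2_mmhg": preds["p2_mmhg"] + rng.normal(0, spec.sd_pressure, n)
        if spec.sd_pressure > 0 else preds["p2_mmhg"],
        "p3_mmhg": preds["p3_mmhg"] + rng.normal(0, spec.sd_pressure, n)
        if spec.sd_pressure > 0 else preds["p3_mmhg"],
    }, columns=MEASUREMENT_COLUMNS)
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as UTF-8 comma CSV with a deterministic float format."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")


_SERIES_PAIRS = {
    "flow": ("q_l_min", "q_meas_l_min"),
    "P1": ("p1_mmhg", "p1_mmhg"),
    "P2": ("p2_mmhg", "p2_mmhg"),
    "P3": ("p3_mmhg", "p3_mmhg"),
}


def paired_series_from_tables(
    predictions: pd.DataFrame, measurements: pd.DataFrame
) -> dict[str, PairedSeries]:
    """Join a prediction and a measurement table on combo_id.

    Returns one :class:`PairedSeries` per variable (flow, P1, P2, P3).
    """
    merged = predictions.merge(
        measurements, on="combo_id", suffixes=("_pred", "_meas"),
        validate="one_to_one",
    )
    if merged.empty:
        raise LibraryError("no overlapping combo_id between tables")
    out = {}
    for label, (pred_col, meas_col) in _SERIES_PAIRS.items():
        pc = pred_col if pred_col in merged else f"{pred_col}_pred"
        mc = meas_col if meas_col in merged else f"{meas_col}_meas"
        out[label] = PairedSeries(
            label=label,
            predicted=tuple(merged[pc]),
            measured=tuple(merged[mc]),
            combo_ids=tuple(merged["combo_id"]),
        )
    return out


def validate_tables(
    predictions: pd.DataFrame, measurements: pd.DataFrame
) -> dict[str, ValidationReport]:
    """Agreement reports for flow, P1, P2 and P3 between two tables."""
    series = paired_series_from_tables(predictions, measurements)
    return {label: compute_validation_stats(s) for label, s in series.items()}


def reports_to_frame(reports: dict[str, ValidationReport]) -> pd.DataFrame:
    """One row per series label, columns = report fields."""
    return pd.DataFrame([r.as_dict() for r in reports.values()])
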