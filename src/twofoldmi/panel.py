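"""Core data structures for longitudinal panel data with missingness.

A panel holds values for N patients over T consecutive, 1-based time
blocks.  Time-dependent variables have one value slot per (patient,
block); time-independent variables have a single slot per patient.
Missing cells carry an out-of-band sentinel (NaN for continuous, code -1
for categorical) and are additionally tracked by a boolean mask, which
is the authoritative record of observedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "Term",
    "EVENT",
    "TIME",
    "LongitudinalPanel",
    "SurvivalOutcome",
    "ImputedSet",
    "PanelError",
    "read_panel",
    "write_panel",
    "read_outcome",
    "write_outcome",
    "complete_records",
]

CONTINUOUS = "continuous"
BINARY = "binary"
CATEGORICAL = "categorical"


class PanelError(ValueError):
    """Raised for schema violations and malformed panel input."""


@dataclass(frozen=True)
class VariableSpec:
    """Per-variable metadata.

    Parameters
    ----------
    name : str
        Variable identifier.
    kind : {"continuous", "binary", "categorical"}
        Measurement type.  ``binary`` is categorical with exactly two
        levels.
    levels : tuple of str, optional
        Declared category labels; required for binary/categorical.
    time_dependent : bool
        Whether the variable has one value per time block.
    imputable : bool
        Whether missing cells of this variable are ever imputed.
    reference : str, optional
        Reference level used when the variable is dummy-encoded in the
        substantive model.  Defaults to the first declared level.
    anchor_level : str, optional
        Monotone-category constraint: patients only ever observed at
        this level are deterministically held at it at all blocks, and
        stochastic imputation is restricted to the remaining levels.
    """

    name: str
    kind: str
    levels: Optional[tuple[str, ...]] = None
    time_dependent: bool = True
    imputable: bool = True
    reference: Optional[str] = None
    anchor_level: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, BINARY, CATEGORICAL):
            raise PanelError(f"unknown variable kind {self.kind!r}")
        if self.kind == CONTINUOUS:
            if self.levels is not None:
                raise PanelError(f"{self.name}: continuous variable with levels")
        else:
            if self.levels is None or len(self.levels) < 2:
                raise PanelError(f"{self.name}: categorical variable needs >=2 levels")
            if self.kind == BINARY and len(self.levels) != 2:
                raise PanelError(f"{self.name}: binary variable needs exactly 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise PanelError(f"{self.name}: duplicate levels")
            if self.reference is not None and self.reference not in self.levels:
                raise PanelError(f"{self.name}: reference {self.reference!r} not a level")
            if self.anchor_level is not None and self.anchor_level not in self.levels:
                raise PanelError(f"{self.name}: anchor {self.anchor_level!r} not a level")

    @property
    def is_categorical(self) -> bool:
        return self.kind in (BINARY, CATEGORICAL)

    @property
    def ref_level(self) -> Optional[str]:
        if not self.is_categorical:
            return None
        return self.reference if self.reference is not None else self.levels[0]

    def code_of(self, label: str) -> int:
        try:
            return self.levels.index(label)
        except (ValueError, AttributeError):
            raise PanelError(f"{self.name}: unknown level {label!r}") from None


class Term(NamedTuple):
    """Reference to a variable slot: (name, block) with block=None for
    time-independent variables and outcome terms."""

    var: str
    block: Optional[int]


#: Outcome terms usable in imputation-model predictor sets.
EVENT = Term("@event", None)
TIME = Term("@time", None)
OUTCOME_TERMS = (EVENT, TIME)


@dataclass
class SurvivalOutcome:
    """Per-patient event indicator and follow-up time."""

    event: np.ndarray
    time: np.ndarray

    def __post_init__(self) -> None:
        self.event = np.asarray(self.event, dtype=np.int8)
        self.time = np.asarray(self.time, dtype=np.float64)
        if self.event.shape != self.time.shape or self.event.ndim != 1:
            raise PanelError("event and time must be equal-length vectors")
        if not np.all((self.event == 0) | (self.event == 1)):
            raise PanelError("event indicator must be 0/1")
        if not np.all(self.time > 0):
            raise PanelError("follow-up times must be strictly positive")

    @property
    def n(self) -> int:
        return self.event.shape[0]

    def subset(self, idx: np.ndarray) -> "SurvivalOutcome":
        return SurvivalOutcome(self.event[idx].copy(), self.time[idx].copy())


class LongitudinalPanel:
    """Rectangular patient x block x variable store with a missingness
    mask.

    Values are held per variable: continuous variables as float arrays
    with NaN in missing cells, categorical variables as integer level
    codes with -1 in missing cells.  ``mask(name)`` is True where a
    value is observed (or filled by imputation, for completed panels).
    """

    def __init__(
        self,
        patients: Sequence,
        blocks: Sequence[int],
        specs: Sequence[VariableSpec],
    ) -> None:
        self.patients = np.asarray(patients)
        if len(set(self.patients.tolist())) != len(self.patients):
            raise PanelError("duplicate patient identifiers")
        blocks = [int(b) for b in blocks]
        if blocks != list(range(1, len(blocks) + 1)):
            raise PanelError("blocks must be consecutive 1..T")
        self.blocks: tuple[int, ...] = tuple(blocks)
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise PanelError("duplicate variable names in schema")
        self.specs: dict[str, VariableSpec] = {s.name: s for s in specs}
        self._values: dict[str, np.ndarray] = {}
        self._mask: dict[str, np.ndarray] = {}
        n = len(self.patients)
        t = len(self.blocks)
        for s in specs:
            shape = (n, t) if s.time_dependent else (n,)
            if s.is_categorical:
                self._values[s.name] = np.full(shape, -1, dtype=np.int16)
            else:
                self._values[s.name] = np.full(shape, np.nan, dtype=np.float64)
            self._mask[s.name] = np.zeros(shape, dtype=bool)

    # -- basic geometry -------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def spec(self, name: str) -> VariableSpec:
        try:
            return self.specs[name]
        except KeyError:
            raise PanelError(f"unknown variable {name!r}") from None

    def variables(self) -> list[str]:
        return list(self.specs)

    # -- cell access ----------------------------------------------------
    def values(self, name: str) -> np.ndarray:
        """Raw value array (codes for categorical)."""
        self.spec(name)
        return self._values[name]

    def mask(self, name: str) -> np.ndarray:
        self.spec(name)
        return self._mask[name]

    def labels(self, name: str) -> np.ndarray:
        """Values as declared level labels (object array), None if missing."""
        s = self.spec(name)
        if not s.is_categorical:
            raise PanelError(f"{name} is not categorical")
        codes = self._values[name]
        out = np.full(codes.shape, None, dtype=object)
        for i, lev in enumerate(s.levels):
            out[codes == i] = lev
        return out

    def set_cells(self, name: str, where: np.ndarray, values: np.ndarray) -> None:
        """Write values into the cells selected by boolean ``where`` and
        mark them observed.  Mask/value consistency is re-asserted."""
        s = self.spec(name)
        arr = self._values[name]
        if where.shape != arr.shape:
            raise PanelError(f"{name}: selector shape mismatch")
        vals = np.asarray(values)
        if vals.shape == where.shape:
            vals = vals[where]
        arr[where] = vals
        self._mask[name][where] = True
        self._assert_consistent(name)

    def _assert_consistent(self, name: str) -> None:
        s = self.spec(name)
        m = self._mask[name]
        v = self._values[name]
        filled = (v >= 0) if s.is_categorical else ~np.isnan(v)
        if not np.array_equal(m, filled):
            raise PanelError(f"{name}: mask and values disagree")

    def validate(self) -> None:
        for name in self.specs:
            self._assert_consistent(name)

    def is_complete(self, name: Optional[str] = None) -> bool:
        names = [name] if name else list(self.specs)
        return all(self._mask[n].all() for n in names)

    def copy(self) -> "LongitudinalPanel":
        out = LongitudinalPanel(self.patients, self.blocks, list(self.specs.values()))
        for name in self.specs:
            out._values[name] = self._values[name].copy()
            out._mask[name] = self._mask[name].copy()
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LongitudinalPanel):
            return NotImplemented
        if (
            not np.array_equal(self.patients, other.patients)
            or self.blocks != other.blocks
            or list(self.specs) != list(other.specs)
        ):
            return False
        for name in self.specs:
            if not np.array_equal(self._mask[name], other._mask[name]):
                return False
            a, b = self._values[name], other._values[name]
            m = self._mask[name]
            if not np.array_equal(a[m], b[m]):
                return False
        return True


@dataclass
class ImputedSet:
    """K completed copies of a panel plus provenance."""

    panels: list[LongitudinalPanel]
    method: str
    config: dict = field(default_factory=dict)
    seeds: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        for p in self.panels:
            if not p.is_complete():
                raise PanelError("imputed panels must be complete")

    @property
    def k(self) -> int:
        return len(self.panels)


# ---------------------------------------------------------------------------
# IO: long/wide delimited layouts
# ---------------------------------------------------------------------------

def _parse_value(spec: VariableSpec, raw) -> float:
    if spec.is_categorical:
        return spec.code_of(str(raw))
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise PanelError(f"{spec.name}: non-numeric value {raw!r}") from None


def read_panel(
    path,
    schema: Sequence[VariableSpec],
    layout: str = "long",
    blocks: Optional[int] = None,
) -> LongitudinalPanel:
    """Read a panel from delimited text.

    Long layout: columns ``patient, block, variable, value``; rows for
    time-independent variables leave ``block`` empty.  Wide layout: one
    row per patient, ``<var>_<block>`` columns for time-dependent
    variables, bare ``<var>`` columns for time-independent ones.
    """
    if layout not in ("long", "wide"):
        raise PanelError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    by_name = {s.name: s for s in schema}

    if layout == "long":
        required = {"patient", "block", "variable", "value"}
        if not required.issubset(df.columns):
            raise PanelError(f"long layout needs columns {sorted(required)}")
        patients = list(dict.fromkeys(df["patient"]))
        block_vals = sorted(int(b) for b in df["block"] if b != "")
        t = blocks if blocks is not None else (block_vals[-1] if block_vals else 1)
        panel = LongitudinalPanel(patients, range(1, t + 1), schema)
        pidx = {p: i for i, p in enumerate(panel.patients.tolist())}
        seen: set[tuple] = set()
        for row in df.itertuples(index=False):
            name = row.variable
            if name not in by_name:
                raise PanelError(f"unknown variable {name!r}")
            s = by_name[name]
            if row.value == "":
                continue
            i = pidx[row.patient]
            if s.time_dependent:
                if row.block == "":
                    raise PanelError(f"{name}: time-dependent row without block")
                b = int(row.block)
                if not 1 <= b <= t:
                    raise PanelError(f"{name}: block {b} outside 1..{t}")
                key = (row.patient, b, name)
                loc = (i, b - 1)
            else:
                key = (row.patient, None, name)
                loc = (i,)
            if key in seen:
                raise PanelError(f"duplicate cell {key}")
            seen.add(key)
            panel._values[name][loc] = _parse_value(s, row.value)
            panel._mask[name][loc] = True
    else:
        if "patient" not in df.columns:
            raise PanelError("wide layout needs a 'patient' column")
        patients = df["patient"].tolist()
        td_cols: list[tuple[str, str, int]] = []
        ti_cols: list[tuple[str, str]] = []
        max_block = 0
        for col in df.columns:
            if col == "patient":
                continue
            if col in by_name:
                if by_name[col].time_dependent:
                    raise PanelError(f"{col}: time-dependent variable needs _<block> columns")
                ti_cols.append((col, col))
                continue
            base, _, suff = col.rpartition("_")
            if base in by_name and suff.isdigit():
                td_cols.append((col, base, int(suff)))
                max_block = max(max_block, int(suff))
            else:
                raise PanelError(f"unknown column {col!r}")
        t = blocks if blocks is not None else max(max_block, 1)
        for col, name, b in td_cols:
            if not 1 <= b <= t:
                raise PanelError(f"column {col!r}: block {b} outside declared 1..{t}")
        panel = LongitudinalPanel(patients, range(1, t + 1), schema)
        for col, name, b in td_cols:
            s = by_name[name]
            raw = df[col]
            obs = raw != ""
            vals = [_parse_value(s, v) for v in raw[obs]]
            panel._values[name][obs.to_numpy(), b - 1] = vals
            panel._mask[name][obs.to_numpy(), b - 1] = True
        for col, name in ti_cols:
            s = by_name[name]
            raw = df[col]
            obs = raw != ""
            vals = [_parse_value(s, v) for v in raw[obs]]
            panel._values[name][obs.to_numpy()] = vals
            panel._mask[name][obs.to_numpy()] = True

    panel.validate()
    return panel


def _format_value(spec: VariableSpec, code_or_val) -> str:
    if spec.is_categorical:
        return spec.levels[int(code_or_val)]
    return repr(float(code_or_val))


def write_panel(panel: LongitudinalPanel, path, layout: str = "long") -> None:
    """Write a panel as delimited text; inverse of :func:`read_panel`."""
    if layout == "long":
        rows = []
        for name, s in panel.specs.items():
            v, m = panel._values[name], panel._mask[name]
            for i, pid in enumerate(panel.patients.tolist()):
                if s.time_dependent:
                    for b in panel.blocks:
                        if m[i, b - 1]:
                            rows.append((pid, b, name, _format_value(s, v[i, b - 1])))
                elif m[i]:
                    rows.append((pid, "", name, _format_value(s, v[i])))
        pd.DataFrame(rows, columns=["patient", "block", "variable", "value"]).to_csv(
            path, index=False
        )
    elif layout == "wide":
        data: dict[str, list] = {"patient": panel.patients.tolist()}
        for name, s in panel.specs.items():
            v, m = panel._values[name], panel._mask[name]
            if s.time_dependent:
                for b in panel.blocks:
                    col = [
                        _format_value(s, v[i, b - 1]) if m[i, b - 1] else ""
                        for i in range(panel.n_patients)
                    ]
                    data[f"{name}_{b}"] = col
            else:
                data[name] = [
                    _format_value(s, v[i]) if m[i] else "" for i in range(panel.n_patients)
                ]
        pd.DataFrame(data).to_csv(path, index=False)
    else:
        raise PanelError(f"unknown layout {layout!r}")


def read_outcome(path) -> tuple[np.ndarray, SurvivalOutcome]:
    df = pd.read_csv(path)
    for col in ("patient", "event", "time"):
        if col not in df.columns:
            raise PanelError("outcome file needs columns patient,event,time")
    return df["patient"].to_numpy(), SurvivalOutcome(
        df["event"].to_numpy(), df["time"].to_numpy()
    )


def write_outcome(patients, outcome: SurvivalOutcome, path) -> None:
    pd.DataFrame(
        {"patient": patients, "event": outcome.event, "time": outcome.time}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Complete-records extraction
# ---------------------------------------------------------------------------

def complete_records(
    panel: LongitudinalPanel,
    outcome: SurvivalOutcome,
    at_block: int,
    covariates: Optional[Sequence[str]] = None,
) -> tuple[LongitudinalPanel, SurvivalOutcome, np.ndarray]:
    """Subset to patients fully observed on the substantive-model
    covariates at ``at_block``.

    Returns the subset panel, the matching outcome subset and the
    boolean keep-mask over patients.  ``covariates`` defaults to every
    variable in the panel.
    """
    if at_block not in panel.blocks:
        raise PanelError(f"block {at_block} outside 1..{panel.n_blocks}")
    if outcome.n != panel.n_patients:
        raise PanelError("outcome length does not match panel")
    names = list(covariates) if covariates is not None else panel.variables()
    keep = np.ones(panel.n_patients, dtype=bool)
    for name in names:
        s = panel.spec(name)
        m = panel.mask(name)
        keep &= m[:, at_block - 1] if s.time_dependent else m
    sub = LongitudinalPanel(
        panel.patients[keep], panel.blocks, list(panel.specs.values())
    )
    for name in panel.specs:
        sub._values[name] = panel._values[name][keep].copy()
        sub._mask[name] = panel._mask[name][keep].copy()
    return sub, outcome.subset(keep), keep
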