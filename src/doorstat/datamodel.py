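"""Domain types and IO for DOOR (desirability of outcome ranking) analyses.

A DOOR outcome is an ordinal, patient-level composite ordered from most to
least desirable overall patient experience.  The types here carry the two
canonical representations of a two-arm DOOR dataset:

* :class:`PatientDataset` — one row per participant (arm, ordinal category,
  optional binary component-outcome flags, optional analysis weight and
  propensity score);
* :class:`DoorTable` — the 2×K arm-by-category count table, which is the
  sufficient statistic for all unweighted analyses.

Categories are indexed 1..K with 1 the *most* desirable (typically "alive
with no events") and K the least desirable (typically death).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoorCategoryScheme",
    "PatientDataset",
    "DoorTable",
    "GradingKey",
    "EffectEstimate",
    "SchemaError",
    "ValidationError",
    "read_patient_table",
    "read_count_table",
    "tabulate",
    "expand",
    "load_fixture",
    "FIXTURE_NAMES",
]


class SchemaError(ValueError):
    """Raised when an input file does not match the declared schema."""


class ValidationError(ValueError):
    """Raised when data violate a structural invariant (duplicate ids, empty arm...)."""


@dataclass(frozen=True)
class DoorCategoryScheme:
    """Ordered DOOR category labels, most desirable first.

    Parameters
    ----------
    labels
        Category names, index 0 = most desirable ... index K-1 = least
        desirable.  Downstream code uses 1-based category indices.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(self.labels) < 2:
            raise ValidationError("a DOOR scheme needs at least 2 categories")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("category labels must be unique")

    @property
    def K(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        """1-based index of a category label."""
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise SchemaError(f"unknown DOOR category label: {label!r}") from None

    @classmethod
    def generic(cls, K: int) -> "DoorCategoryScheme":
        return cls(tuple(f"category {k}" for k in range(1, K + 1)))


@dataclass(frozen=True)
class DoorTable:
    """2×K count table: row 0 = experimental arm, row 1 = control arm.

    Columns follow the scheme's desirability order (most desirable first).
    """

    counts: np.ndarray
    arms: tuple[str, str] = ("experimental", "control")
    scheme: DoorCategoryScheme | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape[0] != 2 or c.ndim != 2 or c.shape[1] < 2:
            raise ValidationError(f"count table must be 2×K with K ≥ 2, got shape {c.shape}")
        if np.any(c < 0):
            raise ValidationError("counts must be nonnegative")
        if np.any(c.sum(axis=1) < 1):
            raise ValidationError("both arms must contain at least one participant")
        object.__setattr__(self, "counts", c.astype(np.int64))
        if self.scheme is None:
            object.__setattr__(self, "scheme", DoorCategoryScheme.generic(c.shape[1]))
        elif self.scheme.K != c.shape[1]:
            raise ValidationError("scheme has a different number of categories than the table")

    @property
    def K(self) -> int:
        return self.counts.shape[1]

    @property
    def n1(self) -> int:
        return int(self.counts[0].sum())

    @property
    def n2(self) -> int:
        return int(self.counts[1].sum())

    def swapped(self) -> "DoorTable":
        """The same contrast with arm roles reversed."""
        return DoorTable(self.counts[::-1].copy(), (self.arms[1], self.arms[0]), self.scheme)

    def dichotomized(self, cut: int) -> "DoorTable":
        """Collapse to 2 levels: categories 1..cut vs the rest."""
        if not 1 <= cut < self.K:
            raise ValueError(f"cut must be in 1..{self.K - 1}, got {cut}")
        c = self.counts
        out = np.column_stack([c[:, :cut].sum(axis=1), c[:, cut:].sum(axis=1)])
        lab = self.scheme.labels
        scheme = DoorCategoryScheme(
            (" / ".join(lab[:cut]) if cut <= 2 else f"{lab[0]} ... {lab[cut - 1]}",
             " / ".join(lab[cut:]) if self.K - cut <= 2 else f"{lab[cut]} ... {lab[-1]}")
        )
        return DoorTable(out, self.arms, scheme)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.arms), columns=list(self.scheme.labels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="arm")


@dataclass
class PatientDataset:
    """Per-participant records of a two-arm DOOR study.

    ``df`` columns: ``id``, ``arm``, ``category`` (1-based int; NaN allowed and
    excluded from analyses with a warning), one column per component flag
    (0/1/NaN), ``weight`` (nonnegative, default 1) and optionally
    ``propensity`` (in (0,1)).
    """

    df: pd.DataFrame
    scheme: DoorCategoryScheme
    arms: tuple[str, str] = ("experimental", "control")
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.df
        for col in ("id", "arm", "category"):
            if col not in df.columns:
                raise SchemaError(f"patient table lacks required column {col!r}")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValidationError(f"duplicate participant id: {dup!r}")
        bad_arm = ~df["arm"].isin(self.arms)
        if bad_arm.any():
            raise ValidationError(
                f"arm labels {sorted(df.loc[bad_arm, 'arm'].unique())} not in {self.arms}"
            )
        for arm in self.arms:
            if not (df["arm"] == arm).any():
                raise ValidationError(f"arm {arm!r} is empty")
        cat = df["category"]
        ok = cat.isna() | (cat.ge(1) & cat.le(self.scheme.K) & (cat == cat.round()))
        if not ok.all():
            row = df.index[~ok][0]
            raise SchemaError(
                f"row {row}: DOOR category {cat[row]!r} outside 1..{self.scheme.K}"
            )
        n_missing = int(cat.isna().sum())
        if n_missing:
            warnings.warn(
                f"{n_missing} record(s) with missing DOOR category are excluded from analyses",
                UserWarning,
                stacklevel=2,
            )
        if "weight" not in df.columns:
            df = df.copy()
            df["weight"] = 1.0
            self.df = df
        w = df["weight"]
        if (w < 0).any() or w.isna().any():
            raise ValidationError("weights must be nonnegative and non-missing")
        for arm in self.arms:
            if w[df["arm"] == arm].sum() <= 0:
                raise ValidationError(f"all weights are zero in arm {arm!r}")
        if "propensity" in df.columns:
            ps = df["propensity"].dropna()
            if ((ps <= 0) | (ps >= 1)).any():
                bad = df.index[(df["propensity"] <= 0) | (df["propensity"] >= 1)][0]
                raise ValidationError(f"row {bad}: propensity score must lie strictly in (0,1)")

    @property
    def experimental(self) -> str:
        return self.arms[0]

    @property
    def control(self) -> str:
        return self.arms[1]

    def complete(self) -> pd.DataFrame:
        """Rows with a recorded DOOR category (the analysis set)."""
        return self.df[self.df["category"].notna()]

    def arm_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        cc = self.complete()
        return cc[cc["arm"] == self.experimental], cc[cc["arm"] == self.control]

    @property
    def n1(self) -> int:
        return int((self.complete()["arm"] == self.experimental).sum())

    @property
    def n2(self) -> int:
        return int((self.complete()["arm"] == self.control).sum())

    def with_weights(self, weights: np.ndarray) -> "PatientDataset":
        df = self.df.copy()
        df["weight"] = np.asarray(weights, dtype=float)
        return PatientDataset(df, self.scheme, self.arms, self.components)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass(frozen=True)
class GradingKey:
    """Partial-credit grades on the 0–100 scale, one per DOOR category.

    The most desirable category is pinned at 100, the least desirable at 0.
    Non-monotone intermediate grades are legal (the contour sweep covers the
    full square) but flagged via :attr:`is_monotone`.
    """

    grades: tuple[float, ...]

    def __post_init__(self) -> None:
        g = tuple(float(x) for x in self.grades)
        object.__setattr__(self, "grades", g)
        if len(g) < 2:
            raise ValidationError("a grading key needs at least 2 grades")
        if g[0] != 100.0:
            raise ValidationError("grade of the most desirable category must be 100")
        if g[-1] != 0.0:
            raise ValidationError("grade of the least desirable category must be 0")
        if any(not 0.0 <= x <= 100.0 for x in g):
            raise ValidationError("grades must lie in [0, 100]")
        if not self.is_monotone:
            warnings.warn("grading key is not monotone nonincreasing", UserWarning, stacklevel=2)

    @property
    def K(self) -> int:
        return len(self.grades)

    @property
    def is_monotone(self) -> bool:
        return all(a >= b for a, b in zip(self.grades, self.grades[1:]))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.grades, dtype=float)


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate with its confidence interval and test.

    ``scale`` is one of ``probability`` (DOOR probabilities), ``grade-points``
    (partial-credit mean differences) or ``ratio`` (win ratio / win odds).
    """

    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    p_value: float | None = None
    method: str = ""
    scale: str = "probability"
    n1: int | None = None
    n2: int | None = None
    extras: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("confidence level must be in (0,1)")
        if not (self.ci_low <= self.estimate + 1e-12 and self.estimate <= self.ci_high + 1e-12):
            raise ValueError("confidence bounds must bracket the estimate")
        if self.scale == "probability" and not (-1e-12 <= self.ci_low and self.ci_high <= 1 + 1e-12):
            raise ValueError("probability-scale values must lie in [0,1]")

    def as_dict(self) -> dict:
        d = {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "p_value": self.p_value,
            "method": self.method,
            "scale": self.scale,
            "n1": self.n1,
            "n2": self.n2,
        }
        d.update(self.extras)
        return d

    def as_percent_text(self) -> str:
        """Render a probability-scale estimate the conventional way: '51.0% (47.6%, 54.3%)'."""
        if self.scale != "probability":
            raise ValueError("percent rendering applies to probability-scale estimates")
        return (
            f"{100 * self.estimate:.1f}% "
            f"({100 * self.ci_low:.1f}%, {100 * self.ci_high:.1f}%)"
        )


# ---------------------------------------------------------------------------
# Readers / converters


def read_patient_table(
    path,
    scheme: DoorCategoryScheme,
    arms: tuple[str, str] = ("experimental", "control"),
    columns: Mapping[str, str] | None = None,
    components: Sequence[str] = (),
) -> PatientDataset:
    """Read a patient-level CSV into a validated :class:`PatientDataset`.

    ``columns`` maps canonical names (``id``, ``arm``, ``category``,
    ``weight``, ``propensity``) to the file's column names when they differ.
    The DOOR category may be given as a 1-based integer index or as a label
    from ``scheme``.  Component flags are preserved as-is, including missing
    values; no complete-case filtering happens here.
    """
    raw = pd.read_csv(path)
    colmap = {"id": "id", "arm": "arm", "category": "door_category"}
    if columns:
        colmap.update(columns)
    for canon in ("id", "arm", "category"):
        if colmap[canon] not in raw.columns:
            raise SchemaError(f"column {colmap[canon]!r} (for {canon!r}) missing from {path}")
    df = pd.DataFrame(
        {
            "id": raw[colmap["id"]],
            "arm": raw[colmap["arm"]].astype(str),
            "category": _coerce_categories(raw[colmap["category"]], scheme),
        }
    )
    for comp in components:
        if comp not in raw.columns:
            raise SchemaError(f"component column {comp!r} missing from {path}")
        df[comp] = pd.to_numeric(raw[comp], errors="raise")
    for opt in ("weight", "propensity"):
        src = colmap.get(opt, opt)
        if src in raw.columns:
            df[opt] = pd.to_numeric(raw[src], errors="raise")
    return PatientDataset(df, scheme, arms, tuple(components))


def _coerce_categories(col: pd.Series, scheme: DoorCategoryScheme) -> pd.Series:
    out = pd.to_numeric(col, errors="coerce")
    text = col[out.isna() & col.notna()]
    for idx, val in text.items():
        k = scheme.index_of(str(val))  # raises SchemaError on unknown label
        out[idx] = k
    bad = out.notna() & ~(out.ge(1) & out.le(scheme.K) & (out == out.round()))
    if bad.any():
        row = out.index[bad][0]
        raise SchemaError(f"row {row}: DOOR category {col[row]!r} outside 1..{scheme.K}")
    return out.astype(float)


def read_count_table(
    path, arms: tuple[str, str] | None = None, scheme: DoorCategoryScheme | None = None
) -> DoorTable:
    """Read a 2×K count table CSV (rows = arms, first column = arm name)."""
    frame = pd.read_csv(path, index_col=0)
    if frame.shape[0] != 2:
        raise SchemaError(f"count table must have exactly 2 arm rows, got {frame.shape[0]}")
    table_arms = arms if arms is not None else (str(frame.index[0]), str(frame.index[1]))
    if arms is not None:
        try:
            frame = frame.loc[list(arms)]
        except KeyError as exc:
            raise SchemaError(f"arm {exc.args[0]!r} not present in {path}") from None
    if scheme is None:
        scheme = DoorCategoryScheme(tuple(str(c) for c in frame.columns))
    return DoorTable(frame.to_numpy(), table_arms, scheme)


def tabulate(data: PatientDataset) -> DoorTable:
    """Collapse a patient-level dataset to its 2×K count table."""
    exp, ctl = data.arm_frames()
    K = data.scheme.K
    counts = np.zeros((2, K), dtype=np.int64)
    for row, frame in enumerate((exp, ctl)):
        cats = frame["category"].astype(int).to_numpy()
        counts[row] = np.bincount(cats, minlength=K + 1)[1:]
    return DoorTable(counts, data.arms, data.scheme)


def expand(table: DoorTable) -> PatientDataset:
    """Reconstruct a unit-weight patient-level dataset from a count table."""
    rows = []
    i = 0
    for arm_idx, arm in enumerate(table.arms):
        for k in range(table.K):
            for _ in range(int(table.counts[arm_idx, k])):
                rows.append((f"p{i:05d}", arm, k + 1))
                i += 1
    df = pd.DataFrame(rows, columns=["id", "arm", "category"])
    df["category"] = df["category"].astype(float)
    return PatientDataset(df, table.scheme, table.arms)


# ---------------------------------------------------------------------------
# Packaged fixture: the DORI-05 cUTI/pyelonephritis trial (doripenem vs
# levofloxacin) analyzed with the 5-level ARLG DOOR outcome.

_DORI05_SCHEME = DoorCategoryScheme(
    (
        "Alive with no events",
        "Alive with 1 event",
        "Alive with 2 events",
        "Alive with 3 events",
        "Death",
    )
)

_DORI05_ARMS = ("doripenem", "levofloxacin")

_DORI05_DOOR = np.array(
    [
        [263, 93, 16, 1, 1],
        [253, 111, 9, 1, 0],
    ]
)

# component name -> (no-event, event) counts per arm; "no event" is the more
# desirable level of each binary component outcome
_DORI05_COMPONENTS = {
    "Absence of clinical success": np.array([[293, 81], [261, 113]]),
    "Infectious complications": np.array([[351, 23], [369, 5]]),
    "Non-fatal SAEs": np.array([[349, 25], [360, 14]]),
    "Death": np.array([[373, 1], [374, 0]]),
}

FIXTURE_NAMES = ("dori05_door", "dori05_components", "dori05_patients")


def load_fixture(name: str):
    """Load a packaged fixture.

    ``dori05_door`` → 5-level :class:`DoorTable`; ``dori05_components`` →
    dict of per-component 2×2 tables (no event = more desirable);
    ``dori05_patients`` → the DOOR table expanded to patient level.
    """
    if name == "dori05_door":
        return DoorTable(_DORI05_DOOR.copy(), _DORI05_ARMS, _DORI05_SCHEME)
    if name == "dori05_components":
        return {
            comp: DoorTable(
                c.copy(), _DORI05_ARMS, DoorCategoryScheme((f"No {comp.lower()}", comp))
            )
            for comp, c in _DORI05_COMPONENTS.items()
        }
    if name == "dori05_patients":
        return expand(load_fixture("dori05_door"))
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
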