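"""Core data containers and long-format panel I/O.

The interchange format is a long CSV with columns ``id, time, y, treatment,
period, period2``.  ``time`` is an equally spaced integer index within person
(any aggregation to equal spacing happens upstream).  Missing outcomes are
empty cells or ``NA`` and are retained as missing: they are skipped in
likelihood contributions (missing-at-random).

Period is coded 0, 1, 2, 3 so that the growth-curve intercept is the
pre-intervention level and the slope is the per-period increment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PanelDataset",
    "LatentTruth",
    "ModelSpec",
    "read_panel",
    "write_panel",
    "preset_spec",
    "PRESET_SPECS",
]


@dataclass(frozen=True)
class PanelDataset:
    """A person-period panel in rectangular (N x T_max) layout.

    Attributes
    ----------
    person_ids : list
        N person identifiers, in row order of the arrays below.
    times : ndarray, shape (N, T_max)
        Integer time index per person, unit-spaced; -1 marks padding rows
        beyond a person's series length.
    y : ndarray, shape (N, T_max)
        Observed outcome; NaN marks missing (or padded) cells.
    treatment : ndarray, shape (N,)
        Binary treatment indicator per person.
    period : ndarray, shape (N, T_max)
        Study-period code in {0, 1, 2, 3}, non-decreasing within person.
    period2 : ndarray, shape (N, T_max)
        1 during the intervention period, else 0.
    """

    person_ids: list
    times: np.ndarray
    y: np.ndarray
    treatment: np.ndarray
    period: np.ndarray
    period2: np.ndarray

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def t_lengths(self) -> np.ndarray:
        """T_i: number of time rows per person (observed or missing)."""
        return (self.times >= 0).sum(axis=1)

    @property
    def obs_mask(self) -> np.ndarray:
        """True where y is an actual (non-missing, non-padded) observation."""
        return np.isfinite(self.y) & (self.times >= 0)

    @property
    def n_total(self) -> int:
        """n = sum_i T_i counting non-missing outcomes."""
        return int(self.obs_mask.sum())

    @property
    def valid_mask(self) -> np.ndarray:
        """True on real (non-padded) person-time rows, missing y included."""
        return self.times >= 0

    def __post_init__(self):
        N = len(self.person_ids)
        for name in ("times", "y", "period", "period2"):
            arr = getattr(self, name)
            if arr.shape[0] != N:
                raise ValueError(f"{name} has {arr.shape[0]} rows, expected {N}")
        if self.treatment.shape != (N,):
            raise ValueError("treatment must be one value per person")
        if not np.isin(self.treatment, [0, 1]).all():
            raise ValueError("treatment must be binary (0/1)")
        for i, pid in enumerate(self.person_ids):
            t = self.times[i][self.times[i] >= 0]
            if t.size == 0:
                raise ValueError(f"person {pid!r} has no time points")
            if t.size > 1 and not np.array_equal(np.diff(t), np.ones(t.size - 1)):
                raise ValueError(
                    f"person {pid!r}: time index must be strictly increasing "
                    "and unit-spaced"
                )
            p = self.period[i][: t.size]
            if (np.diff(p) < 0).any():
                raise ValueError(f"person {pid!r}: period must be non-decreasing")
            p2 = self.period2[i][: t.size]
            if not np.isin(p2, [0, 1]).all():
                raise ValueError(f"person {pid!r}: period2 must be binary (0/1)")

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with one row per real person-time cell."""
        rows = []
        for i, pid in enumerate(self.person_ids):
            m = self.times[i] >= 0
            rows.append(
                pd.DataFrame(
                    {
                        "id": pid,
                        "time": self.times[i][m],
                        "y": self.y[i][m],
                        "treatment": int(self.treatment[i]),
                        "period": self.period[i][m],
                        "period2": self.period2[i][m],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def concat(self, other: "PanelDataset") -> "PanelDataset":
        """Concatenate two panels with disjoint person ids."""
        if set(self.person_ids) & set(other.person_ids):
            raise ValueError("person ids overlap")
        return from_frame(pd.concat([self.to_frame(), other.to_frame()], ignore_index=True))


@dataclass(frozen=True)
class LatentTruth:
    """Latent generating quantities aligned with a :class:`PanelDataset`.

    ``regimes`` holds S_{i,t} in 1..S (0 on padding); ``baseline_path`` and
    ``iiv_path`` are the realized mu_{i,t} and IIV_{i,t} (variance scale);
    ``random_effects`` maps names to per-person draws.
    """

    regimes: np.ndarray
    baseline_path: np.ndarray
    iiv_path: np.ndarray
    random_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.regimes.shape != self.baseline_path.shape != self.iiv_path.shape:
            raise ValueError("latent arrays must share one shape")
        valid = self.regimes > 0
        if not (self.iiv_path[valid] > 0).all():
            raise ValueError("iiv_path must be strictly positive")


_BASELINE_COMPONENTS = ("constant", "GCM", "RW", "GCM+RS", "RW+RS")
_IIV_COMPONENTS = ("constant", "GCM", "RS")

# Random-effect SD switches recognised by the inference module; True = freely
# estimated, False = fixed at zero (and the matching person effects collapse).
_RE_NAMES = (
    "sigma_phi",
    "sigma_beta0",
    "sigma_beta1",
    "sigma_betaIIV0",
    "sigma_betaIIV1",
    "sigma_delta_mu",
    "sigma_delta_iiv",
)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of which change components a model carries."""

    baseline_component: str = "constant"
    iiv_component: str = "constant"
    n_regimes: int = 1
    rs_target: tuple = ()
    random_effects: Mapping[str, bool] = field(
        default_factory=lambda: {n: False for n in _RE_NAMES}
    )
    sign_constraints: Mapping[str, str] = field(default_factory=dict)
    prior_profile: str = "simulation"
    fixed: Mapping[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        if self.baseline_component not in _BASELINE_COMPONENTS:
            raise ValueError(f"unknown baseline component {self.baseline_component!r}")
        if self.iiv_component not in _IIV_COMPONENTS:
            raise ValueError(f"unknown IIV component {self.iiv_component!r}")
        has_rs = self.baseline_component.endswith("+RS") or self.iiv_component == "RS"
        if has_rs and self.n_regimes < 2:
            raise ValueError("regime-switching components require n_regimes >= 2")
        if not has_rs and self.n_regimes != 1:
            raise ValueError("n_regimes > 1 without any RS component")
        expected_targets = set()
        if self.baseline_component.endswith("+RS"):
            expected_targets.add("baseline")
        if self.iiv_component == "RS":
            expected_targets.add("iiv")
        if set(self.rs_target) != expected_targets:
            raise ValueError(f"rs_target must be {sorted(expected_targets)}")
        unknown = set(self.random_effects) - set(_RE_NAMES)
        if unknown:
            raise ValueError(f"unknown random-effect switches: {sorted(unknown)}")

    @property
    def has_rs(self) -> bool:
        return self.n_regimes > 1

    def re_free(self, name: str) -> bool:
        return bool(self.random_effects.get(name, False))

    def to_yaml(self, path) -> None:
        d = {
            "name": self.name,
            "baseline_component": self.baseline_component,
            "iiv_component": self.iiv_component,
            "n_regimes": self.n_regimes,
            "rs_target": list(self.rs_target),
            "random_effects": dict(self.random_effects),
            "sign_constraints": dict(self.sign_constraints),
            "prior_profile": self.prior_profile,
            "fixed": {k: float(v) for k, v in self.fixed.items()},
        }
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["rs_target"] = tuple(d.get("rs_target", ()))
        return cls(**d)

    def with_profile(self, profile: str) -> "ModelSpec":
        return replace(self, prior_profile=profile)


def _spec(name, baseline, iiv, S, rs_target, free_res, **kw):
    re = {n: False for n in _RE_NAMES}
    for n in free_res:
        re[n] = True
    return ModelSpec(
        baseline_component=baseline,
        iiv_component=iiv,
        n_regimes=S,
        rs_target=tuple(rs_target),
        random_effects=re,
        name=name,
        **kw,
    )


def _build_presets():
    sign_mu = {"delta_mu": ">=0"}
    sign_iiv = {"delta_iiv": ">=0"}
    presets = {
        # Gradual-change-only candidates
        "GCM": _spec("GCM", "GCM", "constant", 1, (), ["sigma_beta0"]),
        "RW": _spec("RW", "RW", "constant", 1, (), ["sigma_beta0"]),
        # Baseline regime switching; slope held common across persons so the
        # abrupt-shift terms carry the between-person change differences.
        "GCM-RS2": _spec(
            "GCM-RS2", "GCM+RS", "constant", 2, ("baseline",),
            ["sigma_beta0", "sigma_delta_mu"], sign_constraints=sign_mu,
        ),
        "RW-RS2": _spec(
            "RW-RS2", "RW+RS", "constant", 2, ("baseline",),
            ["sigma_beta0", "sigma_delta_mu"], sign_constraints=sign_mu,
        ),
        "GCM-RS3": _spec(
            "GCM-RS3", "GCM+RS", "constant", 3, ("baseline",),
            ["sigma_beta0", "sigma_delta_mu"], sign_constraints=sign_mu,
        ),
        "RW-RS3": _spec(
            "RW-RS3", "RW+RS", "constant", 3, ("baseline",),
            ["sigma_beta0", "sigma_delta_mu"], sign_constraints=sign_mu,
        ),
        # IIV change candidates: person-specific growth intercept and slope,
        # person-specific AR.
        "GCM+RS2-IIV": _spec(
            "GCM+RS2-IIV", "GCM", "RS", 2, ("iiv",),
            ["sigma_phi", "sigma_beta0", "sigma_beta1", "sigma_delta_iiv"],
            sign_constraints=sign_iiv,
        ),
        "GCM+GCM-IIV": _spec(
            "GCM+GCM-IIV", "GCM", "GCM", 1, (),
            ["sigma_phi", "sigma_beta0", "sigma_beta1",
             "sigma_betaIIV0", "sigma_betaIIV1"],
        ),
        # Diagnostic hybrid: growth curve plus a residual random-walk drift in
        # the baseline, used to probe for unmodelled time variation via sigma_e.
        "GCM+RW": _spec("GCM+RW", "RW", "constant", 1, (), ["sigma_beta0"],
                        fixed={}, ),
    }
    return presets


PRESET_SPECS = _build_presets()


def preset_spec(name: str) -> ModelSpec:
    """Return the named candidate-model specification.

    Valid names: GCM, RW, GCM-RS2, RW-RS2, GCM-RS3, RW-RS3, GCM+RS2-IIV,
    GCM+GCM-IIV (plus the GCM+RW diagnostic hybrid).
    """
    try:
        return PRESET_SPECS[name]
    except KeyError:
        raise KeyError(
            f"unknown model preset {name!r}; valid presets: "
            + ", ".join(sorted(PRESET_SPECS))
        ) from None


_DEFAULT_COLS = {"id": "id", "time": "time", "y": "y",
                 "treatment": "treatment", "period": "period",
                 "period2": "period2"}


def from_frame(df: pd.DataFrame) -> PanelDataset:
    """Build a :class:`PanelDataset` from a long-format DataFrame."""
    if len(df) == 0:
        return empty_panel()
    if df.duplicated(subset=["id", "time"]).any():
        dup = df[df.duplicated(subset=["id", "time"])].iloc[0]
        raise ValueError(
            f"duplicated (person, time) row: id={dup['id']!r}, time={dup['time']}"
        )
    for col, default in (("treatment", 0), ("period", 0), ("period2", 0)):
        if col not in df.columns:
            df = df.assign(**{col: default})
    ids = list(pd.unique(df["id"]))
    groups = {pid: g.sort_values("time") for pid, g in df.groupby("id", sort=False)}
    t_max = max(len(g) for g in groups.values())
    N = len(ids)
    times = np.full((N, t_max), -1, dtype=np.int64)
    y = np.full((N, t_max), np.nan)
    period = np.zeros((N, t_max), dtype=np.int64)
    period2 = np.zeros((N, t_max), dtype=np.int64)
    treatment = np.zeros(N, dtype=np.int64)
    for i, pid in enumerate(ids):
        g = groups[pid]
        T = len(g)
        times[i, :T] = g["time"].to_numpy()
        y[i, :T] = pd.to_numeric(g["y"]).to_numpy(dtype=float)
        period[i, :T] = g["period"].to_numpy()
        period2[i, :T] = g["period2"].to_numpy()
        tr = pd.unique(g["treatment"])
        if len(tr) != 1:
            raise ValueError(f"person {pid!r}: treatment must be constant")
        treatment[i] = tr[0]
    return PanelDataset(ids, times, y, treatment, period, period2)


def read_panel(path, column_map: Mapping[str, str] | None = None) -> PanelDataset:
    """Read a long-format CSV panel.

    ``column_map`` maps canonical names (id, time, y, treatment, period,
    period2) to the file's column names.  Covariate columns are optional and
    default to 0.  Missing outcomes may be empty cells or ``NA``.
    """
    cols = dict(_DEFAULT_COLS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, na_values=["NA"])
    rename = {v: k for k, v in cols.items() if v in df.columns}
    df = df.rename(columns=rename)
    for required in ("id", "time", "y"):
        if required not in df.columns:
            raise ValueError(f"column {cols[required]!r} not found in {path}")
    return from_frame(df)


def write_panel(data: PanelDataset, path) -> None:
    """Write a panel to CSV; read_panel(write_panel(d)) is the identity."""
    if data.n_persons == 0:
        pd.DataFrame(columns=list(_DEFAULT_COLS)).to_csv(path, index=False)
        return
    data.to_frame().to_csv(path, index=False, na_rep="NA")


def empty_panel() -> PanelDataset:
    """Degenerate N=0 panel (useful only for I/O round-trips)."""
    z = np.zeros((0, 0))
    return PanelDataset([], z.astype(np.int64), z.copy(),
                        np.zeros(0, dtype=np.int64),
                        z.astype(np.int64), z.astype(np.int64))


def design_panel(n_persons: int, n_times: int) -> PanelDataset:
    """Deterministic simulation design: even treatment split, Period2 = 1 in
    the second half of the series, Period in four equal blocks, y all missing
    (to be filled by the simulator)."""
    ids = list(range(1, n_persons + 1))
    times = np.tile(np.arange(1, n_times + 1), (n_persons, 1))
    y = np.full((n_persons, n_times), np.nan)
    treatment = (np.arange(n_persons) >= n_persons / 2).astype(np.int64)
    block = n_times / 4.0
    period = np.minimum((np.arange(n_times) / block).astype(np.int64), 3)
    period = np.tile(period, (n_persons, 1))
    period2 = np.tile((np.arange(n_times) >= n_times / 2).astype(np.int64),
                      (n_persons, 1))
    return PanelDataset(ids, times, y, treatment, period, period2)
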