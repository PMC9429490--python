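"""Normalized public-health-problem risk score, scenario grid and level table.

The score combines a scenario (flood severity F, help H, preparedness P, each
on the 0-10 rating scale) with four standardized coefficients from the fitted
latent model:

    C1: severity -> php        (positive: worse floods, worse problems)
    C2: help -> php            (negative: more help, fewer problems)
    C3: preparedness -> php    (negative)
    C4: preparedness -> help   (positive; C2*C4 carries the mediated effect)

Because C2 and C3 act against problems, the score uses the sign-adjusted form

    S = [C1 F + |C2|(10-H) + |C3|(10-P) + |C2 C4|(10-H)(10-P)]
        / [C1 + |C2| + |C3| + 10 |C2 C4|]

which is 10 in the worst case (F=10, H=P=0) and 0 in the best (F=0, H=P=10).
Enumerating all 11^3 = 1331 integer scenarios and binning the scores at the
k/11 empirical quantiles yields an 11-level risk scale with a fixed colour
per level for mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LoadingSet",
    "Scenario",
    "RiskGrid",
    "RiskLevelTable",
    "PUBLISHED_LOADINGS",
    "LEVEL_COLOURS",
    "score",
    "normalizer",
    "enumerate_grid",
    "build_level_table",
    "level_to_colour",
]


@dataclass(frozen=True)
class LoadingSet:
    """The four standardized coefficients driving the risk score."""

    C1: float
    C2: float
    C3: float
    C4: float

    def __post_init__(self) -> None:
        den = self.C1 + abs(self.C2) + abs(self.C3) + 10.0 * abs(self.C2 * self.C4)
        if den <= 0:
            raise ValueError("normalizer C1 + |C2| + |C3| + 10|C2*C4| must be positive")

    @classmethod
    def from_fit(cls, fit) -> "LoadingSet":
        """Extract C1..C4 from a fitted model's standardized solution."""
        from .sem_engine import standardized_solution

        paths = standardized_solution(fit).paths
        return cls(
            C1=paths[("severity", "php")],
            C2=paths[("help", "php")],
            C3=paths[("preparedness", "php")],
            C4=paths[("preparedness", "help")],
        )

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "LoadingSet":
        return cls(C1=float(d["C1"]), C2=float(d["C2"]), C3=float(d["C3"]), C4=float(d["C4"]))

    def to_dict(self) -> dict[str, float]:
        return {"C1": self.C1, "C2": self.C2, "C3": self.C3, "C4": self.C4}


#: The published standardized solution (severity->php, help->php,
#: preparedness->php, preparedness->help).
PUBLISHED_LOADINGS = LoadingSet(C1=0.287, C2=-0.029, C3=-0.008, C4=0.452)


@dataclass(frozen=True)
class Scenario:
    """A per-region flood scenario on the 0-10 scale."""

    F: float
    H: float
    P: float

    def __post_init__(self) -> None:
        for name, v in (("F", self.F), ("H", self.H), ("P", self.P)):
            if not 0.0 <= v <= 10.0:
                raise ValueError(f"scenario value {name}={v} outside [0, 10]")


def normalizer(loadings: LoadingSet) -> float:
    """Denominator C1 + |C2| + |C3| + 10|C2*C4| of the score."""
    value = (
        loadings.C1
        + abs(loadings.C2)
        + abs(loadings.C3)
        + 10.0 * abs(loadings.C2 * loadings.C4)
    )
    if value == 0:
        raise ValueError("score normalizer is zero")
    return value


def _score_arrays(
    f: np.ndarray,
    h: np.ndarray,
    p: np.ndarray,
    loadings: LoadingSet,
    eq10_printed: bool,
) -> np.ndarray:
    c1, c2, c3 = loadings.C1, abs(loadings.C2), abs(loadings.C3)
    c24 = abs(loadings.C2 * loadings.C4)
    den = normalizer(loadings)
    if not eq10_printed:
        num = c1 * f + c2 * (10 - h) + c3 * (10 - p) + c24 * (10 - h) * (10 - p)
    else:
        # Compatibility mode reproducing the published expanded polynomial,
        # whose linear help coefficient double-counts |C2| (printed -0.18908
        # where the exact expansion gives -0.16008 for the published
        # loadings).  Kept selectable because whether the deployed
        # application used the printed polynomial is unknowable.
        const = 10 * c2 + 10 * c3 + 100 * c24
        num = c1 * f - (2 * c2 + 10 * c24) * h - (c3 + 10 * c24) * p + c24 * h * p + const
    return num / den


def score(
    scenario: Scenario | tuple[float, float, float],
    loadings: LoadingSet = PUBLISHED_LOADINGS,
    *,
    eq10_printed: bool = False,
) -> float:
    """Normalized risk score S in [0, 10] for one scenario."""
    if not isinstance(scenario, Scenario):
        scenario = Scenario(*scenario)
    return float(
        _score_arrays(
            np.asarray(scenario.F),
            np.asarray(scenario.H),
            np.asarray(scenario.P),
            loadings,
            eq10_printed,
        )
    )


@dataclass
class RiskGrid:
    """All scored scenarios on the integer 0..10 grid (F-major, then H, P)."""

    entries: pd.DataFrame  # columns F, H, P, S
    loadings: LoadingSet

    @property
    def scores(self) -> np.ndarray:
        return self.entries["S"].to_numpy()

    def to_csv(self, path_or_buf, table: "RiskLevelTable | None" = None) -> None:
        out = self.entries.copy()
        if table is not None:
            out["level"] = table.level(out["S"].to_numpy())
            out["colour"] = [LEVEL_COLOURS[lv][0] for lv in out["level"]]
        out.to_csv(path_or_buf, index=False)


def enumerate_grid(
    loadings: LoadingSet = PUBLISHED_LOADINGS, *, eq10_printed: bool = False
) -> RiskGrid:
    """Score every integer scenario: 11 x 11 x 11 = 1331 cases."""
    pts = np.arange(11)
    f, h, p = np.meshgrid(pts, pts, pts, indexing="ij")
    f, h, p = f.ravel(), h.ravel(), p.ravel()
    s = _score_arrays(f.astype(float), h.astype(float), p.astype(float), loadings, eq10_printed)
    df = pd.DataFrame({"F": f, "H": h, "P": p, "S": s})
    return RiskGrid(entries=df, loadings=loadings)


#: Risk level -> (colour name, hex RGB).  Names follow the published 11-level
#: legend; RGB values use the common named-colour convention, frozen here so
#: maps are bit-reproducible.
LEVEL_COLOURS: dict[int, tuple[str, str]] = {
    10: ("Dark Red", "#8B0000"),
    9: ("Maroon", "#800000"),
    8: ("Red", "#FF0000"),
    7: ("Orange Red", "#FF4500"),
    6: ("Orange", "#FFA500"),
    5: ("Gold", "#FFD700"),
    4: ("Yellow", "#FFFF00"),
    3: ("Greenish Yellow", "#ADFF2F"),
    2: ("Yellowish Green", "#9ACD32"),
    1: ("Forest Green", "#228B22"),
    0: ("Green", "#008000"),
}


def level_to_colour(level: int) -> tuple[str, str]:
    """Colour name and hex RGB for a risk level 0..10."""
    if level not in LEVEL_COLOURS:
        raise ValueError(f"risk level must be an integer in 0..10, got {level}")
    return LEVEL_COLOURS[level]


@dataclass
class RiskLevelTable:
    """Percentile cutoffs partitioning scores into the 11 risk levels.

    ``cutoffs`` are the k/11 empirical quantiles (k = 1..10) of the
    calibration scores; ``level(S)`` counts cutoffs strictly below S, so a
    score equal to a cutoff falls in the lower level.
    """

    cutoffs: np.ndarray  # 10 nondecreasing thresholds

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        if self.cutoffs.shape != (10,):
            raise ValueError("a risk level table needs exactly 10 cutoffs")
        if np.any(np.diff(self.cutoffs) < 0):
            raise ValueError("cutoffs must be nondecreasing")

    def level(self, s):
        """Risk level(s) 0..10 for score(s) ``s``; ties go to the lower level."""
        arr = np.asarray(s, dtype=float)
        lev = np.searchsorted(self.cutoffs, arr, side="left")
        return lev if arr.ndim else int(lev)

    def colour(self, s) -> tuple[str, str]:
        return level_to_colour(self.level(float(s)))

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "cutoffs": [float(c) for c in self.cutoffs],
                "colours": {int(k): list(v) for k, v in sorted(LEVEL_COLOURS.items())},
            },
            sort_keys=False,
        )

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def from_yaml(cls, text: str) -> "RiskLevelTable":
        d = yaml.safe_load(text)
        return cls(cutoffs=np.asarray(d["cutoffs"], dtype=float))

    @classmethod
    def read_yaml(cls, path) -> "RiskLevelTable":
        with open(path) as fh:
            return cls.from_yaml(fh.read())


def build_level_table(grid: RiskGrid | np.ndarray) -> RiskLevelTable:
    """Percentile-bin calibration scores into the 11-level table.

    Cutoffs sit at the k/11 empirical quantiles (linear interpolation) of the
    grid scores.  A degenerate all-equal grid collapses every scenario into
    level 0 and triggers a warning.
    """
    scores = grid.scores if isinstance(grid, RiskGrid) else np.asarray(grid, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot calibrate a level table on an empty grid")
    if np.ptp(scores) == 0:
        warnings.warn("all calibration scores identical; every scenario maps to level 0")
    qs = np.arange(1, 11) / 11.0
    cutoffs = np.quantile(scores, qs, method="linear")
    return RiskLevelTable(cutoffs=cutoffs)
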