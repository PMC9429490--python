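"""Seeded synthetic survey, demographic and region generators.

The flood-risk analysis assumes questionnaire data with a four-latent-variable
causal structure: flood *severity* and *preparedness* are exogenous (and
correlated), preparedness drives *help*, and all three feed the
*public-health-problems* (php) latent.  Each latent is measured by a block of
0-10 rating items (10 severity, 4 preparedness, 4 help, 10 php; 28 items in
all).  No survey data were ever deposited for this design, so everything
downstream is exercised on synthetic data drawn from the standardized
structural model, calibrated to the published standardized solution.

All generators are pure functions of an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon, mapping, shape

__all__ = [
    "GeneratorConfig",
    "SurveyDataset",
    "Region",
    "RegionSet",
    "LATENTS",
    "DEFAULT_STRUCTURAL_PATHS",
    "TABLE_MARGINALS",
    "generate_survey",
    "implied_population_covariance",
    "latent_covariance",
    "generate_demographics",
    "generate_regions",
]

#: Latent variables in canonical order (exogenous first, then topologically).
LATENTS = ("severity", "preparedness", "help", "php")

#: Standardized structural paths of the published solution: severity->php,
#: help->php, preparedness->php, preparedness->help.
DEFAULT_STRUCTURAL_PATHS = {
    "b_F_PHP": 0.287,
    "b_H_PHP": -0.029,
    "b_P_PHP": -0.008,
    "b_P_H": 0.452,
}

DEFAULT_N_ITEMS = {"severity": 10, "preparedness": 4, "help": 4, "php": 10}

#: Mapping from latent scale (unit variance, mean 0) to the 0-10 rating scale:
#: value = SCALE_CENTER + SCALE_SLOPE * z, so +-3 SD spans the 11 choices.
SCALE_CENTER = 5.0
SCALE_SLOPE = 10.0 / 6.0

_PATH_EDGES = {
    # parameter name -> (target latent, source latent)
    "b_F_PHP": ("php", "severity"),
    "b_H_PHP": ("php", "help"),
    "b_P_PHP": ("php", "preparedness"),
    "b_P_H": ("help", "preparedness"),
}


def item_names(n_items: Mapping[str, int]) -> list[str]:
    """Column names for the item blocks: sev01..sev10, prep1.., help1.., php01.."""
    prefixes = {"severity": "sev", "preparedness": "prep", "help": "help", "php": "php"}
    names: list[str] = []
    for block in LATENTS:
        k = n_items[block]
        width = 2 if k >= 10 else 1
        names.extend(f"{prefixes[block]}{i:0{width}d}" for i in range(1, k + 1))
    return names


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic questionnaire generator.

    ``structural_paths`` are standardized coefficients of the generating model;
    ``exo_correlation_F_P`` is the correlation between the exogenous severity
    and preparedness latents.  The default 0.534 is calibrated so the
    population explained variance of the php equation equals the published
    7.7%.  ``measurement_loading`` is the common standardized indicator
    loading (the published report prints no measurement loadings; 0.7 is a
    typical well-fitting survey value).
    """

    n_respondents: int = 560
    structural_paths: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURAL_PATHS)
    )
    exo_correlation_F_P: float = 0.534
    measurement_loading: float = 0.7
    n_items: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_ITEMS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents <= 0:
            raise ValueError("n_respondents must be positive")
        if not -1.0 <= self.exo_correlation_F_P <= 1.0:
            raise ValueError("exo_correlation_F_P must lie in [-1, 1]")
        if not 0.0 < self.measurement_loading <= 1.0:
            raise ValueError("measurement_loading must lie in (0, 1]")
        missing = set(_PATH_EDGES) - set(self.structural_paths)
        if missing:
            raise ValueError(f"structural_paths missing {sorted(missing)}")
        if set(self.n_items) != set(LATENTS) or any(
            int(v) <= 0 for v in self.n_items.values()
        ):
            raise ValueError("n_items must give a positive count per latent block")
        latent_covariance(self)  # raises on negative implied residual variance

    @property
    def total_items(self) -> int:
        return int(sum(self.n_items.values()))

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data.get("generator", data))


def _structural_matrices(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (B, Psi) for the latent system, residual variances solved so
    every latent has unit variance.  Raises if a residual variance would be
    negative, naming the offending structural equation."""
    m = len(LATENTS)
    idx = {name: i for i, name in enumerate(LATENTS)}
    B = np.zeros((m, m))
    for pname, (dst, src) in _PATH_EDGES.items():
        B[idx[dst], idx[src]] = float(config.structural_paths[pname])
    psi = np.zeros((m, m))
    psi[idx["severity"], idx["severity"]] = 1.0
    psi[idx["preparedness"], idx["preparedness"]] = 1.0
    phi = float(config.exo_correlation_F_P)
    psi[idx["severity"], idx["preparedness"]] = phi
    psi[idx["preparedness"], idx["severity"]] = phi
    A = np.linalg.inv(np.eye(m) - B)
    # topological order of endogenous latents: help before php
    for name in ("help", "php"):
        k = idx[name]
        var_k = (A @ psi @ A.T)[k, k]
        resid = 1.0 - var_k
        if resid < 0:
            raise ValueError(
                f"structural equation for '{name}' implies negative residual "
                f"variance ({resid:.4f}); reduce its path coefficients"
            )
        psi[k, k] += resid
    return B, psi


def latent_covariance(config: GeneratorConfig) -> np.ndarray:
    """Exact covariance of the four latents (unit diagonal by construction)."""
    B, psi = _structural_matrices(config)
    A = np.linalg.inv(np.eye(len(LATENTS)) - B)
    sigma = A @ psi @ A.T
    return (sigma + sigma.T) / 2.0


def implied_population_covariance(config: GeneratorConfig) -> pd.DataFrame:
    """Exact pre-discretization covariance of all items implied by the
    generating equations.

    Each item is ``loading * latent + sqrt(1 - loading^2) * error`` on the
    latent scale, so the item covariance is ``loading^2`` times the latent
    covariance expanded over blocks, with unit diagonal.  Returned as a
    labelled, symmetric positive-definite matrix.
    """
    names = item_names(config.n_items)
    lam = config.measurement_loading
    sig_l = latent_covariance(config)
    block_of = np.repeat(np.arange(len(LATENTS)), [config.n_items[b] for b in LATENTS])
    sigma = lam**2 * sig_l[np.ix_(block_of, block_of)]
    np.fill_diagonal(sigma, 1.0)
    return pd.DataFrame(sigma, index=names, columns=names)


@dataclass
class SurveyDataset:
    """Respondent x item table plus the item->latent block assignment.

    ``items`` holds integers in [0, 10] in survey form, or floats on the
    latent scale when generated with ``discretize=False`` (diagnostic mode).
    """

    items: pd.DataFrame
    block_labels: dict[str, str]
    demographics: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if set(self.items.columns) != set(self.block_labels):
            raise ValueError("block_labels must label exactly the item columns")
        if self.demographics is not None and len(self.demographics) != len(self.items):
            raise ValueError("demographics must have one row per respondent")

    @property
    def n_respondents(self) -> int:
        return len(self.items)

    def block(self, latent: str) -> pd.DataFrame:
        cols = [c for c in self.items.columns if self.block_labels[c] == latent]
        return self.items[cols]

    def validate_survey_scale(self) -> None:
        vals = self.items.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("survey items must be integers on the 0-10 scale")
        if vals.min() < 0 or vals.max() > 10:
            raise ValueError("survey items out of the 0-10 range")

    def to_csv(self, path_or_buf) -> None:
        out = self.items
        if self.demographics is not None:
            out = pd.concat(
                [self.items.reset_index(drop=True), self.demographics.reset_index(drop=True)],
                axis=1,
            )
        out.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, n_items: Mapping[str, int] | None = None) -> "SurveyDataset":
        df = pd.read_csv(path_or_buf)
        names = item_names(n_items or DEFAULT_N_ITEMS)
        missing = [c for c in names if c not in df.columns]
        if missing:
            raise ValueError(f"item columns missing from CSV: {missing}")
        labels = _block_labels(n_items or DEFAULT_N_ITEMS)
        demo_cols = [c for c in df.columns if c not in names]
        demo = df[demo_cols] if demo_cols else None
        return cls(items=df[names], block_labels=labels, demographics=demo)


def _block_labels(n_items: Mapping[str, int]) -> dict[str, str]:
    labels: dict[str, str] = {}
    names = iter(item_names(n_items))
    for block in LATENTS:
        for _ in range(n_items[block]):
            labels[next(names)] = block
    return labels


def round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def generate_survey(config: GeneratorConfig, *, discretize: bool = True) -> SurveyDataset:
    """Draw a synthetic questionnaire dataset from the structural model.

    Latent scores follow the standardized system (all latent variances 1);
    each indicator is ``loading * latent + sqrt(1-loading^2) * noise``.  With
    ``discretize=True`` item values are mapped to the 0-10 rating scale via
    ``5 + (10/6) z``, rounded half-up and clipped; with ``discretize=False``
    the continuous latent-scale values are returned (diagnostic mode, used to
    check the generator against its analytic covariance).

    Deterministic: the same config always yields a bit-identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    sig_l = latent_covariance(config)
    chol = np.linalg.cholesky(sig_l)
    latents = rng.standard_normal((n, len(LATENTS))) @ chol.T
    counts = [config.n_items[b] for b in LATENTS]
    block_of = np.repeat(np.arange(len(LATENTS)), counts)
    lam = config.measurement_loading
    noise = rng.standard_normal((n, int(sum(counts))))
    cont = lam * latents[:, block_of] + np.sqrt(1.0 - lam**2) * noise
    if discretize:
        values = np.clip(round_half_up(SCALE_CENTER + SCALE_SLOPE * cont), 0, 10)
        values = values.astype(np.int64)
    else:
        values = cont
    items = pd.DataFrame(values, columns=item_names(config.n_items))
    return SurveyDataset(items=items, block_labels=_block_labels(config.n_items))


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------

#: Published demographic marginals of the n=560 survey.  Counts per category;
#: numeric variables carry the printed summary and the category bounds used
#: for truncated-normal draws.  The open-ended bounds (youngest adult age 18,
#: oldest 80) are calibrated so the mixture over categories reproduces the
#: printed overall mean age of 53.23 years.
TABLE_MARGINALS: dict = {
    "gender": {"Male": 208, "Female": 352},
    "age_group": {"Under 35": 83, "35-59": 258, "60 and over": 219},
    "marital_status": {"Married": 477, "Single": 70, "Widowed/divorced/separated": 13},
    "education": {
        "None": 20,
        "Elementary": 398,
        "High school": 113,
        "Diploma/Bachelor": 28,
        "Master or higher": 1,
    },
    "occupation": {
        "Farmer": 298,
        "Unemployed": 100,
        "Freelancer": 68,
        "Merchant/vendor": 68,
        "Civil servant": 9,
        "Others": 17,
    },
    "income_group": {
        "No income": 47,
        "Less than 1000": 115,
        "1001-10000": 349,
        "More than 10000": 49,
    },
    "household_group": {"1-3": 118, "4-6": 360, "7 or over": 82},
}

#: Numeric companions: variable -> (mean, sd, {category: (low, high)}).
NUMERIC_FROM_GROUP: dict = {
    "age": (
        53.23,
        16.51,
        "age_group",
        {"Under 35": (18.0, 35.0), "35-59": (35.0, 60.0), "60 and over": (60.0, 80.0)},
    ),
    "household_size": (
        4.79,
        1.66,
        "household_group",
        {"1-3": (0.5, 3.5), "4-6": (3.5, 6.5), "7 or over": (6.5, 12.0)},
    ),
}


def _category_probs(marginal: Mapping[str, float], n: int, var: str) -> tuple[list, np.ndarray]:
    cats = list(marginal)
    vals = np.array([float(marginal[c]) for c in cats])
    total = vals.sum()
    if np.isclose(total, 1.0, atol=1e-6):
        return cats, vals
    if np.isclose(total, n, atol=0.5):
        return cats, vals / total
    raise ValueError(
        f"marginal for '{var}' must sum to n={n} (counts) or to 1 (proportions); got {total}"
    )


def generate_demographics(
    n: int,
    marginals: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a demographic table matching per-variable category marginals.

    Categorical variables are drawn independently from their marginals (the
    published table reports marginals only, so no dependence structure is
    imposed).  Age and household size are drawn from normals with the
    published mean/SD, truncated to the range of the sampled category.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    from scipy.stats import truncnorm

    if marginals is None:
        # default published marginals are counts out of 560; use as proportions
        marginals = {
            var: {c: v / sum(m.values()) for c, v in m.items()}
            for var, m in TABLE_MARGINALS.items()
        }
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for var, marginal in marginals.items():
        cats, probs = _category_probs(marginal, n, var)
        out[var] = rng.choice(np.array(cats, dtype=object), size=n, p=probs)
    for var, (mu, sd, group_var, bounds) in NUMERIC_FROM_GROUP.items():
        if group_var not in out:
            continue
        vals = np.empty(n)
        groups = out[group_var]
        for cat, (lo, hi) in bounds.items():
            mask = groups == cat
            k = int(mask.sum())
            if k:
                a, b = (lo - mu) / sd, (hi - mu) / sd
                vals[mask] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=k, random_state=rng)
        unknown = ~np.isin(groups, list(bounds))
        if unknown.any():
            raise ValueError(f"no numeric bounds for categories {set(groups[unknown])}")
        out[var] = np.round(vals, 1)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Toy region geometries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    region_id: str
    subdistrict: str
    district_id: str
    province_id: str
    geometry: Polygon


@dataclass
class RegionSet:
    """Subdistrict polygons nested in districts nested in one province."""

    regions: list[Region]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        for r in self.regions:
            if r.geometry.is_empty or not r.geometry.is_valid:
                raise ValueError(f"region {r.region_id} has an empty or invalid polygon")

    @property
    def hierarchy(self) -> dict[str, tuple[str, str]]:
        """subdistrict region_id -> (district_id, province_id)"""
        return {r.region_id: (r.district_id, r.province_id) for r in self.regions}

    def by_id(self) -> dict[str, Region]:
        return {r.region_id: r for r in self.regions}

    def to_geojson(self) -> dict:
        features = [
            {
                "type": "Feature",
                "geometry": mapping(r.geometry),
                "properties": {
                    "region_id": r.region_id,
                    "subdistrict": r.subdistrict,
                    "district_id": r.district_id,
                    "province_id": r.province_id,
                },
            }
            for r in self.regions
        ]
        return {"type": "FeatureCollection", "features": features}

    def write_geojson(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh, indent=1)

    @classmethod
    def from_geojson(cls, doc: dict) -> "RegionSet":
        regions = []
        for feat in doc["features"]:
            props = feat["properties"]
            regions.append(
                Region(
                    region_id=props["region_id"],
                    subdistrict=props.get("subdistrict", props["region_id"]),
                    district_id=props["district_id"],
                    province_id=props.get("province_id", "P1"),
                    geometry=shape(feat["geometry"]),
                )
            )
        return cls(regions=regions)

    @classmethod
    def read_geojson(cls, path) -> "RegionSet":
        import json

        with open(path) as fh:
            return cls.from_geojson(json.load(fh))


def generate_regions(
    n_subdistricts: int,
    n_districts: int,
    seed: int = 0,
    *,
    jitter: float = 0.0,
    extent: tuple[float, float, float, float] = (101.5, 17.2, 102.1, 17.8),
) -> RegionSet:
    """Build a toy set of subdistrict polygons tiling a rectangular extent.

    Subdistricts are cells of a grid (optionally jittered along shared grid
    lines so cells stay non-overlapping); they are grouped contiguously into
    districts within a single province.  Purely synthetic stand-in geometry:
    the extent defaults to a rectangle in the Loei region but carries no real
    administrative boundaries.
    """
    if not 1 <= n_districts <= n_subdistricts:
        raise ValueError("need n_subdistricts >= n_districts >= 1")
    if not 0.0 <= jitter < 0.5:
        raise ValueError("jitter must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    ncols = int(np.ceil(np.sqrt(n_subdistricts)))
    nrows = int(np.ceil(n_subdistricts / ncols))
    x0, y0, x1, y1 = extent
    xb = np.linspace(x0, x1, ncols + 1)
    yb = np.linspace(y0, y1, nrows + 1)
    if jitter > 0:
        xb[1:-1] += rng.uniform(-jitter, jitter, ncols - 1) * (x1 - x0) / ncols
        yb[1:-1] += rng.uniform(-jitter, jitter, nrows - 1) * (y1 - y0) / nrows
    # near-equal contiguous district sizes
    sizes = np.full(n_districts, n_subdistricts // n_districts)
    sizes[: n_subdistricts % n_districts] += 1
    district_of = np.repeat(np.arange(n_districts), sizes)
    regions = []
    for i in range(n_subdistricts):
        r, c = divmod(i, ncols)
        poly = Polygon(
            [(xb[c], yb[r]), (xb[c + 1], yb[r]), (xb[c + 1], yb[r + 1]), (xb[c], yb[r + 1])]
        )
        regions.append(
            Region(
                region_id=f"SD{i + 1:02d}",
                subdistrict=f"Subdistrict {i + 1:02d}",
                district_id=f"D{district_of[i] + 1}",
                province_id="P1",
                geometry=poly,
            )
        )
    return RegionSet(regions=regions)
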