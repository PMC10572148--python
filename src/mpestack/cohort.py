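"""Synthetic cohort generation for the MPE/BPE diagnostic study.

The original cohort (111 malignant and 208 benign pleural effusions with
eight tumor-marker concentrations each) is not publicly deposited, so this
module generates seedable synthetic cohorts whose group sizes, demographics
and marker-concentration moments match the published group summaries.

Marker concentrations are strictly positive and heavily right-skewed (the
published standard deviations exceed the means severalfold for most
markers), so margins are modelled as lognormals moment-matched to each
group's (mean, sd), coupled through a Gaussian copula with a configurable
latent correlation matrix.  Ages are truncated normals; gender is assigned
as exact per-group counts.

The published summaries carry no information about correlations or the true
distribution shape; the copula correlation defaults below are plumbing, not
estimates, and nothing downstream that is compared against published
arithmetic depends on them.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markers import ALL_MARKERS, marker_analyte, marker_fluid, validate_marker

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "lognormal_params_from_moments",
    "default_spec_from_table1",
    "default_marker_correlation",
    "generate_cohort",
    "CohortGenerator",
    "read_cohort_csv",
    "write_cohort_csv",
    "COHORT_COLUMNS",
]

#: Column order of the cohort CSV interchange format.
COHORT_COLUMNS = ["patient_id", "group", "age", "gender", *ALL_MARKERS]

AGE_LOWER, AGE_UPPER = 18.0, 100.0


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Parameters (mu, sigma) of a lognormal with the given mean and sd.

    Inverts the lognormal moment equations:
    ``sigma^2 = ln(1 + sd^2/mean^2)`` and ``mu = ln(mean) - sigma^2/2``.
    ``sd = 0`` yields the degenerate point mass at ``mean``.
    """
    if not mean > 0:
        raise ValueError(f"lognormal moment matching requires mean > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    sigma = math.sqrt(sigma2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, sigma


@dataclass(frozen=True)
class GroupSpec:
    """Target composition of one diagnostic group (MPE or BPE)."""

    label: str
    n: int
    age_mean: float
    age_sd: float
    male_count: int
    female_count: int
    #: marker -> (mean, sd) in the analyte's unit (ng/mL for CEA, U/mL otherwise)
    marker_moments: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("MPE", "BPE"):
            raise ValueError(f"group label must be MPE or BPE, got {self.label!r}")
        if self.n <= 0:
            raise ValueError("group size must be positive")
        if self.male_count < 0 or self.female_count < 0:
            raise ValueError("gender counts must be non-negative")
        if self.male_count + self.female_count != self.n:
            raise ValueError(
                f"male_count + female_count must equal n "
                f"({self.male_count}+{self.female_count} != {self.n})"
            )
        for m, (mean, sd) in self.marker_moments.items():
            validate_marker(m)
            if mean <= 0:
                raise ValueError(f"{m}: mean must be > 0, got {mean}")
            if sd < 0:
                raise ValueError(f"{m}: sd must be >= 0, got {sd}")


@dataclass(frozen=True)
class CohortSpec:
    """Full generator specification: two groups plus a latent copula correlation."""

    groups: tuple[GroupSpec, GroupSpec]
    marker_correlation: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if sorted(labels) != ["BPE", "MPE"]:
            raise ValueError(f"need exactly one MPE and one BPE group, got {labels}")
        corr = np.asarray(self.marker_correlation, dtype=float)
        k = len(ALL_MARKERS)
        if corr.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k}, got {corr.shape}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("correlation diagonal must be all 1")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semidefinite")
        object.__setattr__(self, "marker_correlation", corr)

    def group(self, label: str) -> GroupSpec:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)

    def with_sizes(self, n_mpe: int, n_bpe: int) -> "CohortSpec":
        """Copy of the spec with rescaled group sizes (gender split kept proportional)."""
        new_groups = []
        for g in self.groups:
            n = n_mpe if g.label == "MPE" else n_bpe
            male = int(round(n * g.male_count / g.n))
            new_groups.append(replace(g, n=n, male_count=male, female_count=n - male))
        return replace(self, groups=tuple(new_groups))


# Published per-group (mean, sd) summaries: MPE then BPE for each marker.
_TABLE1_MOMENTS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "PE.CEA": ((967.15, 2307.31), (16.80, 105.81)),
    "PE.CA19-9": ((2000.31, 4200.90), (5.74, 12.94)),
    "PE.CA125": ((1807.16, 2473.70), (715.22, 796.83)),
    "PE.CA15-3": ((99.97, 199.45), (7.48, 7.80)),
    "PB.CEA": ((98.16, 254.14), (2.12, 1.74)),
    "PB.CA19-9": ((628.56, 2312.09), (13.88, 40.28)),
    "PB.CA125": ((257.72, 502.10), (155.21, 147.49)),
    "PB.CA15-3": ((38.79, 47.97), (12.01, 9.21)),
}


def default_marker_correlation(
    same_analyte: float = 0.4, same_fluid: float = 0.2, other: float = 0.1
) -> np.ndarray:
    """Default latent correlation: strongest between the PE/PB pair of one
    analyte, weaker between analytes sharing a fluid, weakest otherwise."""
    k = len(ALL_MARKERS)
    corr = np.full((k, k), other)
    for i, a in enumerate(ALL_MARKERS):
        for j, b in enumerate(ALL_MARKERS):
            if i == j:
                corr[i, j] = 1.0
            elif marker_analyte(a) == marker_analyte(b):
                corr[i, j] = same_analyte
            elif marker_fluid(a) == marker_fluid(b):
                corr[i, j] = same_fluid
    return corr


def default_spec_from_table1(seed: int = 0) -> CohortSpec:
    """The built-in cohort spec matching the published group summaries:
    111 MPE (age 60.94 +/- 11.96; 59 M / 52 F) and 208 BPE
    (age 49.78 +/- 19.02; 148 M / 60 F), with all 16 marker (mean, sd) pairs."""
    mpe = GroupSpec(
        label="MPE",
        n=111,
        age_mean=60.94,
        age_sd=11.96,
        male_count=59,
        female_count=52,
        marker_moments={m: v[0] for m, v in _TABLE1_MOMENTS.items()},
    )
    bpe = GroupSpec(
        label="BPE",
        n=208,
        age_mean=49.78,
        age_sd=19.02,
        male_count=148,
        female_count=60,
        marker_moments={m: v[1] for m, v in _TABLE1_MOMENTS.items()},
    )
    return CohortSpec(
        groups=(mpe, bpe),
        marker_correlation=default_marker_correlation(),
        seed=seed,
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, lo: float, hi: float
) -> np.ndarray:
    """Normal draws with out-of-range values resampled (not clipped)."""
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _copula_factor(corr: np.ndarray) -> np.ndarray:
    # eigen factorization tolerates exactly-semidefinite matrices where
    # Cholesky would fail; tiny negative eigenvalues are clipped to zero
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort table from ``spec``.

    Returns a DataFrame with columns ``patient_id, group, age, gender`` and
    the eight marker concentrations.  Identical ``(spec, seed)`` pairs give
    identical tables.  Marker vectors are sampled by pushing correlated
    standard normals (the Gaussian copula) through each marker's
    moment-matched lognormal margin; for lognormal margins this is exactly
    ``exp(mu + sigma * z)``.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    factor = _copula_factor(spec.marker_correlation)

    frames = []
    for g in spec.groups:
        missing = [m for m in ALL_MARKERS if m not in g.marker_moments]
        if missing:
            raise ValueError(f"group {g.label}: missing marker moments for {missing}")
        age = _truncated_normal(rng, g.age_mean, g.age_sd, g.n, AGE_LOWER, AGE_UPPER)
        gender = np.array(["male"] * g.male_count + ["female"] * g.female_count)
        rng.shuffle(gender)
        z = rng.standard_normal((g.n, len(ALL_MARKERS))) @ factor.T
        cols = {}
        for j, m in enumerate(ALL_MARKERS):
            mu, sigma = lognormal_params_from_moments(*g.marker_moments[m])
            cols[m] = np.exp(mu + sigma * z[:, j])
        frames.append(
            pd.DataFrame(
                {"group": g.label, "age": age, "gender": gender, **cols}
            )
        )

    table = pd.concat(frames, ignore_index=True)
    table.insert(
        0,
        "patient_id",
        [f"P{i:04d}" for i in range(1, len(table) + 1)],
    )
    return table[COHORT_COLUMNS]


class CohortGenerator:
    """Thin object wrapper pairing a :class:`CohortSpec` with a seed.

    ``CohortGenerator(spec, seed).sample()`` == ``generate_cohort(spec, seed)``.
    """

    def __init__(self, spec: CohortSpec | None = None, seed: int = 0):
        self.spec = spec if spec is not None else default_spec_from_table1()
        self.seed = seed

    def sample(self) -> pd.DataFrame:
        return generate_cohort(self.spec, self.seed)


def write_cohort_csv(table: pd.DataFrame, path_or_buf) -> None:
    """Serialize a cohort table (UTF-8, LF line endings, '.' decimal point)."""
    table[COHORT_COLUMNS].to_csv(path_or_buf, index=False, lineterminator="\n")


def read_cohort_csv(path_or_buf) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort_csv`."""
    table = pd.read_csv(path_or_buf)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    bad_groups = set(table["group"]) - {"MPE", "BPE"}
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    if table[list(ALL_MARKERS)].isna().any().any():
        rows = table.index[table[list(ALL_MARKERS)].isna().any(axis=1)].tolist()
        raise ValueError(f"missing marker values in rows {rows[:10]}")
    if (table[list(ALL_MARKERS)] <= 0).any().any():
        raise ValueError("marker concentrations must be strictly positive")
    return table[COHORT_COLUMNS]


def cohort_csv_bytes(table: pd.DataFrame) -> bytes:
    """Byte-exact CSV serialization (used for determinism manifests)."""
    buf = io.StringIO()
    write_cohort_csv(table, buf)
    return buf.getvalue().encode("utf-8")
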