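"""Model parameters: transition probabilities, relative risks, utilities, costs.

The decision model compares three implant strategies for displaced femoral
neck fracture — bipolar hemiarthroplasty (BHA), single-bearing total hip
arthroplasty (SB-THA) and dual-mobility THA (DM-THA).  Annual event
probabilities are tabulated for SB-THA by 5-year age band; BHA and DM-THA
probabilities are derived from published relative risks.  Every uncertain
quantity carries a (point, low, high) range and a distribution family used
by the probabilistic sensitivity analysis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "Strategy",
    "Family",
    "ParameterRange",
    "DistributionSpec",
    "AgeBandProbabilities",
    "RelativeRisks",
    "ResolvedParams",
    "ParameterSet",
    "derive_range",
    "derive_strategy_probabilities",
    "composite_utilities",
    "build_distribution",
    "AGE_BANDS",
]

#: z-quantile used throughout for 95% ranges (kept at the conventional
#: printed precision so rule-derived ranges round-trip exactly).
Z95 = 1.96

#: Lower edges of the 5-year age bands covered by the transition table.
AGE_BANDS: tuple[int, ...] = (65, 70, 75, 80, 85)


class Strategy(enum.Enum):
    """The three surgical strategies under comparison."""

    BHA = "BHA"
    SB_THA = "SB-THA"
    DM_THA = "DM-THA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


STRATEGIES: tuple[Strategy, ...] = (Strategy.BHA, Strategy.SB_THA, Strategy.DM_THA)


class Family(enum.Enum):
    """Distribution family assigned to a parameter for the PSA."""

    GAMMA = "gamma"
    LOGNORMAL = "lognormal"
    NORMAL = "normal"
    BETA = "beta"
    FIXED = "fixed"


#: family assignment by parameter role: gamma for costs, log-normal for
#: relative risks, normal for disutilities, beta for utilities and
#: probabilities.
ROLE_FAMILY: dict[str, Family] = {
    "cost": Family.GAMMA,
    "relative_risk": Family.LOGNORMAL,
    "disutility": Family.NORMAL,
    "utility": Family.BETA,
    "probability": Family.BETA,
}


@dataclass(frozen=True)
class ParameterRange:
    """Point estimate with a low/high range and a PSA distribution family.

    ``derived`` marks composite quantities (the post-revision utilities)
    whose point value is recomputed from components at resolution time and
    which are only used directly when explicitly overridden.
    """

    point: float
    low: float
    high: float
    family: Family
    derived: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.point) and math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError("parameter range values must be finite")
        if not (self.low <= self.point <= self.high):
            raise ValueError(
                f"range must satisfy low <= point <= high, got ({self.low}, {self.point}, {self.high})"
            )
        if self.family is Family.FIXED and not (self.low == self.point == self.high):
            raise ValueError("fixed family requires low == point == high")

    @property
    def is_fixed(self) -> bool:
        return self.low == self.high

    @property
    def se(self) -> float:
        """Standard error implied by the 95% range."""
        return (self.high - self.low) / (2.0 * Z95)


def derive_range(point: float, role: str = "cost") -> ParameterRange:
    """Construct a range for a parameter known only by its point estimate.

    The convention is SE = 0.2 x |point|, low/high = point -/+ 1.96 SE.
    Monetary quantities (role ``cost``) are rounded to the nearest yen.
    """
    if not math.isfinite(point):
        raise ValueError("point estimate must be finite")
    family = ROLE_FAMILY[role]
    se = 0.2 * abs(point)
    low = point - Z95 * se
    high = point + Z95 * se
    if role == "cost":
        low, high = round(low), round(high)
    if se == 0.0:
        family = Family.FIXED
    return ParameterRange(point=point, low=low, high=high, family=family)


@dataclass(frozen=True)
class AgeBandProbabilities:
    """Annual SB-THA event probabilities for one 5-year age band."""

    band: tuple[int, int]
    p_dis: float
    p_rev_dis: float
    p_rev_nondis: float

    def __post_init__(self) -> None:
        for name in ("p_dis", "p_rev_dis", "p_rev_nondis"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class RelativeRisks:
    """Relative risks linking DM-THA and BHA event rates to the SB-THA table.

    Only DM-referenced ratios are published, so BHA rates are chained
    through DM (see :func:`derive_strategy_probabilities`).
    """

    rr_dis_dm_vs_sb: float
    rr_dis_dm_vs_bha: float
    rr_rev_dis_bha_vs_dm: float
    rr_rev_nondis_bha_vs_dm: float
    rr_rev_dis_dm_vs_sb: float
    rr_rev_nondis_dm_vs_sb: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")


def composite_utilities(u_well_dm, d_r, d_rr):
    """Post-revision health-state utilities as composites.

    The utility of living with a revised hip is the well post-DM-THA
    utility plus the (negative) revision disutility; likewise after a
    re-revision.  Results are clamped to [0, 1].
    """
    u_r = np.clip(np.asarray(u_well_dm) + np.asarray(d_r), 0.0, 1.0)
    u_rr = np.clip(np.asarray(u_well_dm) + np.asarray(d_rr), 0.0, 1.0)
    return u_r, u_rr


def derive_strategy_probabilities(band: AgeBandProbabilities, rr: RelativeRisks):
    """Per-strategy annual event probabilities for one age band.

    SB-THA values are the tabulated ones.  DM-THA multiplies them by the
    DM-vs-SB relative risks.  No direct BHA-vs-SB ratios are published, so
    BHA is chained through DM: its dislocation probability divides the DM
    rate by the DM-vs-BHA ratio, and its revision probabilities multiply
    the DM rate by the BHA-vs-DM ratios.  Results are clamped to [0, 1];
    any clamping is reported in the returned warnings list.
    """
    warnings: list[str] = []

    def clamp(name: str, value: float) -> float:
        v = float(np.asarray(value))
        if v > 1.0:
            warnings.append(f"{name} clamped from {v:.4g} to 1.0")
            return 1.0
        return max(v, 0.0)

    sb = {"p_dis": band.p_dis, "p_rev_dis": band.p_rev_dis, "p_rev_nondis": band.p_rev_nondis}
    dm = {
        "p_dis": band.p_dis * rr.rr_dis_dm_vs_sb,
        "p_rev_dis": band.p_rev_dis * rr.rr_rev_dis_dm_vs_sb,
        "p_rev_nondis": band.p_rev_nondis * rr.rr_rev_nondis_dm_vs_sb,
    }
    bha = {
        "p_dis": dm["p_dis"] / rr.rr_dis_dm_vs_bha,
        "p_rev_dis": dm["p_rev_dis"] * rr.rr_rev_dis_bha_vs_dm,
        "p_rev_nondis": dm["p_rev_nondis"] * rr.rr_rev_nondis_bha_vs_dm,
    }
    out = {}
    for strat, probs in ((Strategy.BHA, bha), (Strategy.SB_THA, sb), (Strategy.DM_THA, dm)):
        out[strat] = {k: clamp(f"{strat.value}:{k}", v) for k, v in probs.items()}
    return out, warnings


# --------------------------------------------------------------------------
# PSA distribution construction
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """Parameterised sampling distribution for one model input.

    ``a``/``b`` meaning per family: gamma (shape, scale), lognormal
    (log-median, log-sd), normal and truncated normal (mean, sd), beta
    (alpha, beta), fixed (point, unused).
    """

    family: Family
    a: float
    b: float
    truncated: bool = False  # normal truncated to [0, 1] (beta fallback)

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        if self.family is Family.FIXED:
            return np.full(size if size is not None else (), self.a)
        if self.family is Family.GAMMA:
            return rng.gamma(self.a, self.b, size=size)
        if self.family is Family.LOGNORMAL:
            return rng.lognormal(self.a, self.b, size=size)
        if self.family is Family.NORMAL:
            draws = rng.normal(self.a, self.b, size=size)
            if self.truncated:
                draws = np.clip(draws, 0.0, 1.0)
            return draws
        if self.family is Family.BETA:
            return np.clip(rng.beta(self.a, self.b, size=size), 0.0, 1.0)
        raise AssertionError(f"unhandled family {self.family}")  # pragma: no cover


def build_distribution(prange: ParameterRange) -> DistributionSpec:
    """Turn a (point, low, high, family) range into a sampling distribution.

    Method of moments on (point, SE) with SE = (high - low) / (2 x 1.96),
    except the log-normal which is centred so its *median* equals the
    point estimate with log-sd = (ln high - ln low) / (2 x 1.96).  A beta
    whose moments are infeasible (SE^2 >= p(1-p)) falls back to a normal
    truncated to [0, 1].
    """
    se = prange.se
    if se == 0.0 or prange.family is Family.FIXED:
        return DistributionSpec(Family.FIXED, prange.point, 0.0)
    if prange.family is Family.GAMMA:
        if prange.point <= 0:
            raise ValueError("gamma requires a positive point estimate")
        shape = (prange.point / se) ** 2
        scale = se**2 / prange.point
        return DistributionSpec(Family.GAMMA, shape, scale)
    if prange.family is Family.LOGNORMAL:
        if prange.low <= 0 or prange.point <= 0:
            raise ValueError("lognormal requires positive point and bounds")
        sigma = (math.log(prange.high) - math.log(prange.low)) / (2.0 * Z95)
        return DistributionSpec(Family.LOGNORMAL, math.log(prange.point), sigma)
    if prange.family is Family.NORMAL:
        return DistributionSpec(Family.NORMAL, prange.point, se)
    if prange.family is Family.BETA:
        m = prange.point
        if not 0.0 < m < 1.0 or se**2 >= m * (1.0 - m):
            # moments infeasible: truncated normal fallback
            return DistributionSpec(Family.NORMAL, m, se, truncated=True)
        nu = m * (1.0 - m) / se**2 - 1.0
        return DistributionSpec(Family.BETA, m * nu, (1.0 - m) * nu)
    raise AssertionError(f"unhandled family {prange.family}")  # pragma: no cover


# --------------------------------------------------------------------------
# The full parameter set
# --------------------------------------------------------------------------

#: canonical parameter keys -> role, used to assign distribution families
#: and to validate parameter files.
PARAMETER_ROLES: dict[str, str] = {}


def _register(keys, role):
    for k in keys:
        PARAMETER_ROLES[k] = role


_register([f"p_dis_sb_{a}" for a in AGE_BANDS], "probability")
_register([f"p_rev_dis_sb_{a}" for a in AGE_BANDS], "probability")
_register([f"p_rev_nondis_sb_{a}" for a in AGE_BANDS], "probability")
_register(
    [
        "rr_dis_dm_vs_sb",
        "rr_dis_dm_vs_bha",
        "rr_rev_dis_bha_vs_dm",
        "rr_rev_nondis_bha_vs_dm",
        "rr_rev_dis_dm_vs_sb",
        "rr_rev_nondis_dm_vs_sb",
    ],
    "relative_risk",
)
_register(["d_dislocation", "d_r_tha", "d_rr_tha"], "disutility")
_register(
    ["u_well_bha", "u_well_sb", "u_well_dm", "u_well_r_tha", "u_well_rr_tha"],
    "utility",
)
_register(
    [
        "c_dislocation_event",
        "c_implant_bha",
        "c_implant_sb",
        "c_implant_dm",
        "fee_bha",
        "fee_sb",
        "fee_dm",
        "fee_r_tha",
        "c_initial_bha",
        "c_initial_sb",
        "c_initial_dm",
        "c_well_annual",
    ],
    "cost",
)


@dataclass
class ResolvedParams:
    """Concrete model inputs consumed by the simulation engine.

    Every field is either a scalar (deterministic run) or an array over PSA
    samples; the engine broadcasts transparently.  Probabilities are stored
    band-major: ``p_dis[strategy]`` has shape ``(n_bands, ...)``.
    """

    p_dis: dict[Strategy, np.ndarray]
    p_rev_dis: dict[Strategy, np.ndarray]
    p_rev_nondis: dict[Strategy, np.ndarray]
    u_well: dict[Strategy, np.ndarray]
    u_r_tha: np.ndarray
    u_rr_tha: np.ndarray
    d_dislocation: np.ndarray
    d_r_tha: np.ndarray
    d_rr_tha: np.ndarray
    c_dislocation_event: np.ndarray
    c_implant: dict[Strategy, np.ndarray]
    fee: dict[Strategy, np.ndarray]
    fee_r_tha: np.ndarray
    c_initial: dict[Strategy, np.ndarray]
    c_well_annual: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def band_index(self, age: float) -> int:
        """Index of the 5-year band containing ``age`` (clamped to 65-89)."""
        return int(np.clip((math.floor(age) - AGE_BANDS[0]) // 5, 0, len(AGE_BANDS) - 1))

    def probs(self, strategy: Strategy, age: float):
        """(p_dis, p_rev_dis, p_rev_nondis) for ``strategy`` at ``age``."""
        i = self.band_index(age)
        return (
            self.p_dis[strategy][i],
            self.p_rev_dis[strategy][i],
            self.p_rev_nondis[strategy][i],
        )

    def surgery_bundle(self, strategy: Strategy):
        """First-cycle cost: initial-year care + implant + surgical fee."""
        return self.c_initial[strategy] + self.c_implant[strategy] + self.fee[strategy]

    def revision_cost(self):
        """Cost of a revision event: R-THA fee plus a DM implant."""
        return self.fee_r_tha + self.c_implant_dm

    @property
    def c_implant_dm(self):
        return self.c_implant[Strategy.DM_THA]


class ParameterSet:
    """A named collection of :class:`ParameterRange` objects.

    Provides point resolution, per-sample PSA resolution, named overrides
    (used by the one-way sensitivity analysis) and file round-tripping.
    """

    def __init__(self, ranges: Mapping[str, ParameterRange]):
        unknown = set(ranges) - set(PARAMETER_ROLES)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(PARAMETER_ROLES) - set(ranges)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        self.ranges: dict[str, ParameterRange] = dict(ranges)
        self._validate()

    def _validate(self) -> None:
        for key, r in self.ranges.items():
            role = PARAMETER_ROLES[key]
            if role in ("probability", "utility") and not (0.0 <= r.low and r.high <= 1.0):
                raise ValueError(f"{key}: {role} range must lie within [0, 1]")
            if role == "disutility" and not (-1.0 <= r.low and r.high <= 0.0):
                raise ValueError(f"{key}: disutility range must lie within [-1, 0]")
            if role == "cost" and r.low < 0:
                raise ValueError(f"{key}: costs must be non-negative")
            if role == "relative_risk" and r.low <= 0:
                raise ValueError(f"{key}: relative risks must be positive")

    def __getitem__(self, key: str) -> ParameterRange:
        return self.ranges[key]

    def keys(self):
        return self.ranges.keys()

    def point_values(self) -> dict[str, float]:
        return {k: r.point for k, r in self.ranges.items()}

    def with_range(self, key: str, prange: ParameterRange) -> "ParameterSet":
        new = dict(self.ranges)
        new[key] = prange
        return ParameterSet(new)

    # -- sampling ----------------------------------------------------------

    def distributions(self) -> dict[str, DistributionSpec]:
        """PSA distributions for every non-derived parameter."""
        return {
            k: build_distribution(r) for k, r in self.ranges.items() if not r.derived
        }

    def sample(self, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
        """One joint PSA draw per sample; parameters sampled independently."""
        return {k: d.sample(rng, n) for k, d in self.distributions().items()}

    # -- resolution --------------------------------------------------------

    def resolve(self, values: Mapping[str, "np.ndarray | float"] | None = None,
                overrides: Mapping[str, float] | None = None) -> ResolvedParams:
        """Build engine-ready inputs from point estimates or sampled values.

        ``values`` defaults to the point estimates (derived composites are
        recomputed from components).  ``overrides`` pins named parameters —
        including the derived post-revision utilities — to explicit values,
        which is how the one-way sensitivity analysis perturbs the model.
        """
        v: dict = {k: r.point for k, r in self.ranges.items() if not r.derived}
        if values is not None:
            v.update({k: np.asarray(val, dtype=float) for k, val in values.items()})
        overrides = dict(overrides or {})
        u_r, u_rr = composite_utilities(v["u_well_dm"], v["d_r_tha"], v["d_rr_tha"])
        if "u_well_r_tha" in overrides:
            u_r = np.asarray(overrides.pop("u_well_r_tha"), dtype=float)
        if "u_well_rr_tha" in overrides:
            u_rr = np.asarray(overrides.pop("u_well_rr_tha"), dtype=float)
        for k, val in overrides.items():
            if k not in v:
                raise KeyError(f"unknown override {k!r}")
            v[k] = np.asarray(val, dtype=float)

        rr_keys = [k for k, role in PARAMETER_ROLES.items() if role == "relative_risk"]
        rr = {k: v[k] for k in rr_keys}
        warnings: list[str] = []

        def stack(role_probs):
            return np.stack(np.broadcast_arrays(*role_probs))

        def clamped(name, x):
            x = np.asarray(x, dtype=float)
            if np.any(x > 1.0):
                warnings.append(f"{name} clamped to 1.0")
            return np.clip(x, 0.0, 1.0)

        p_dis, p_rev_dis, p_rev_nondis = {}, {}, {}
        sb_dis = [np.asarray(v[f"p_dis_sb_{a}"], dtype=float) for a in AGE_BANDS]
        sb_rd = [np.asarray(v[f"p_rev_dis_sb_{a}"], dtype=float) for a in AGE_BANDS]
        sb_rn = [np.asarray(v[f"p_rev_nondis_sb_{a}"], dtype=float) for a in AGE_BANDS]
        p_dis[Strategy.SB_THA] = stack(sb_dis)
        p_rev_dis[Strategy.SB_THA] = stack(sb_rd)
        p_rev_nondis[Strategy.SB_THA] = stack(sb_rn)
        p_dis[Strategy.DM_THA] = clamped(
            "p_dis_dm", p_dis[Strategy.SB_THA] * rr["rr_dis_dm_vs_sb"])
        p_rev_dis[Strategy.DM_THA] = clamped(
            "p_rev_dis_dm", p_rev_dis[Strategy.SB_THA] * rr["rr_rev_dis_dm_vs_sb"])
        p_rev_nondis[Strategy.DM_THA] = clamped(
            "p_rev_nondis_dm", p_rev_nondis[Strategy.SB_THA] * rr["rr_rev_nondis_dm_vs_sb"])
        p_dis[Strategy.BHA] = clamped(
            "p_dis_bha", p_dis[Strategy.DM_THA] / rr["rr_dis_dm_vs_bha"])
        p_rev_dis[Strategy.BHA] = clamped(
            "p_rev_dis_bha", p_rev_dis[Strategy.DM_THA] * rr["rr_rev_dis_bha_vs_dm"])
        p_rev_nondis[Strategy.BHA] = clamped(
            "p_rev_nondis_bha", p_rev_nondis[Strategy.DM_THA] * rr["rr_rev_nondis_bha_vs_dm"])

        def arr(key):
            return np.asarray(v[key], dtype=float)

        resolved = ResolvedParams(
            p_dis=p_dis,
            p_rev_dis=p_rev_dis,
            p_rev_nondis=p_rev_nondis,
            u_well={
                Strategy.BHA: clamped("u_well_bha", arr("u_well_bha")),
                Strategy.SB_THA: clamped("u_well_sb", arr("u_well_sb")),
                Strategy.DM_THA: clamped("u_well_dm", arr("u_well_dm")),
            },
            u_r_tha=np.clip(np.asarray(u_r, dtype=float), 0.0, 1.0),
            u_rr_tha=np.clip(np.asarray(u_rr, dtype=float), 0.0, 1.0),
            d_dislocation=arr("d_dislocation"),
            d_r_tha=arr("d_r_tha"),
            d_rr_tha=arr("d_rr_tha"),
            c_dislocation_event=arr("c_dislocation_event"),
            c_implant={
                Strategy.BHA: arr("c_implant_bha"),
                Strategy.SB_THA: arr("c_implant_sb"),
                Strategy.DM_THA: arr("c_implant_dm"),
            },
            fee={
                Strategy.BHA: arr("fee_bha"),
                Strategy.SB_THA: arr("fee_sb"),
                Strategy.DM_THA: arr("fee_dm"),
            },
            fee_r_tha=arr("fee_r_tha"),
            c_initial={
                Strategy.BHA: arr("c_initial_bha"),
                Strategy.SB_THA: arr("c_initial_sb"),
                Strategy.DM_THA: arr("c_initial_dm"),
            },
            c_well_annual=arr("c_well_annual"),
            warnings=warnings,
        )
        return resolved

    # -- file round trip ---------------------------------------------------

    _SECTIONS = {
        "transition_probabilities": "probability",
        "relative_risks": "relative_risk",
        "disutilities": "disutility",
        "utilities": "utility",
        "costs": "cost",
    }

    def to_dict(self) -> dict:
        out: dict = {section: {} for section in self._SECTIONS}
        inv = {v: k for k, v in self._SECTIONS.items()}
        for key, r in self.ranges.items():
            section = inv[PARAMETER_ROLES[key]]
            entry: dict = {"point": r.point}
            if not r.is_fixed:
                entry["low"], entry["high"] = r.low, r.high
            if r.derived:
                entry["derived"] = True
            out[section][key] = entry
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "ParameterSet":
        ranges: dict[str, ParameterRange] = {}
        for section, role in cls._SECTIONS.items():
            for key, entry in (data.get(section) or {}).items():
                if key not in PARAMETER_ROLES:
                    raise ValueError(f"unknown parameter {key!r} in section {section!r}")
                if PARAMETER_ROLES[key] != role:
                    raise ValueError(f"parameter {key!r} misfiled under {section!r}")
                point = float(entry["point"])
                derived = bool(entry.get("derived", False))
                if "low" in entry or "high" in entry:
                    low, high = float(entry["low"]), float(entry["high"])
                    family = ROLE_FAMILY[role] if low != high else Family.FIXED
                    ranges[key] = ParameterRange(point, low, high, family, derived=derived)
                elif entry.get("rule_range"):
                    ranges[key] = replace(derive_range(point, role), derived=derived)
                else:
                    ranges[key] = ParameterRange(point, point, point, Family.FIXED, derived=derived)
        return cls(ranges)
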