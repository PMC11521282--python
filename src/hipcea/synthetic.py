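"""Synthetic inputs: Gompertz life tables and randomised parameter sets.

The supplementary life tables behind the published analysis (the 2022
Japanese abridged life table) are not redistributable from the article
text, so the package ships a synthetic stand-in: a two-parameter Gompertz
mortality law calibrated to the order of magnitude of Japanese old-age
mortality.  All pipeline stages run end-to-end on these tables; users with
the official tables can pass them in the same two-column format.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .life_tables import LifeTable, Sex
from .parameters import (
    AGE_BANDS,
    Family,
    ParameterRange,
    ParameterSet,
    derive_range,
)

__all__ = [
    "GompertzSpec",
    "FEMALE_SPEC",
    "MALE_SPEC",
    "make_life_table",
    "write_life_table",
    "default_life_table",
    "packaged_parameters",
    "random_parameter_set",
]


@dataclass(frozen=True)
class GompertzSpec:
    """Gompertz mortality law: hazard(age) = b65 * exp(slope * (age - 65)).

    ``b65`` is the annual hazard at age 65 (per year), ``slope`` the
    log-hazard increase per year of age.  The annual death probability is
    q(age) = 1 - exp(-hazard(age)).
    """

    b65: float
    slope: float
    sex: Sex

    def __post_init__(self) -> None:
        if self.b65 <= 0 or self.slope < 0:
            raise ValueError("Gompertz baseline must be positive and slope non-negative")

    def q(self, age: float) -> float:
        return 1.0 - math.exp(-self.b65 * math.exp(self.slope * (age - 65.0)))


#: Default specs emulate Japanese 2022 old-age mortality magnitudes:
#: female q(75) ~ 0.008, male q(75) ~ 0.017, both rising steeply with age.
FEMALE_SPEC = GompertzSpec(b65=0.0024, slope=0.125, sex=Sex.FEMALE)
MALE_SPEC = GompertzSpec(b65=0.0060, slope=0.105, sex=Sex.MALE)


def make_life_table(spec: GompertzSpec, min_age: int = 65, max_age: int = 100) -> LifeTable:
    """Single-year synthetic life table over [min_age, max_age]."""
    ages = np.arange(min_age, max_age + 1)
    q = np.array([spec.q(a) for a in ages])
    if np.any(q >= 1.0):
        first = int(ages[int(np.argmax(q >= 1.0))])
        raise ValueError(f"Gompertz mortality reaches 1 at age {first}, before max_age")
    return LifeTable(sex=spec.sex, min_age=min_age, q=q)


def write_life_table(table: LifeTable, path: str | Path) -> Path:
    """Write a life table in the delimited format the loader reads."""
    path = Path(path)
    lines = ["age,qx"]
    lines += [f"{table.min_age + i},{qi:.8f}" for i, qi in enumerate(table.q)]
    path.write_text("\n".join(lines) + "\n")
    return path


def default_life_table(sex: Sex | str) -> LifeTable:
    """The bundled synthetic life table for ``sex``."""
    sex = Sex(sex) if not isinstance(sex, Sex) else sex
    return make_life_table(FEMALE_SPEC if sex is Sex.FEMALE else MALE_SPEC)


# sha256 of the packaged parameter fixture; guards against silent edits
_FIXTURE_NAME = "default_parameters.yaml"
_FIXTURE_SHA256 = "f2bd1510d3f8546398987ae23468d171c8edc4087bb38ff71e6ed142cbb64a0c"


def packaged_parameters(verify: bool = True) -> ParameterSet:
    """The packaged decision-model parameter fixture (checksum-pinned)."""
    res = importlib.resources.files("hipcea.data").joinpath(_FIXTURE_NAME)
    raw = res.read_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _FIXTURE_SHA256:
            raise RuntimeError(
                f"parameter fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
            )
    return ParameterSet.from_dict(yaml.safe_load(raw))


def random_parameter_set(
    seed: int,
    prob_bounds: tuple[float, float] = (1e-4, 0.2),
    utility_bounds: tuple[float, float] = (0.3, 1.0),
    cost_bounds: tuple[float, float] = (1e4, 1e7),
    rr_bounds: tuple[float, float] = (0.25, 2.0),
    disutility_bounds: tuple[float, float] = (-0.4, -0.01),
) -> ParameterSet:
    """A random but always-valid parameter set for property tests.

    Ranges are rule-derived (SE = 0.2 x point) and clipped to each role's
    support.  The tabulated probabilities are rescaled downward if the
    drawn relative risks would push any strategy's competing event
    probabilities near 1, so generated sets always pass validation.
    """
    rng = np.random.default_rng(seed)

    def u(lo, hi):
        return float(rng.uniform(lo, hi))

    def clipped_range(point, role, lo, hi):
        r = derive_range(point, role)
        low, high = max(r.low, lo), min(r.high, hi)
        low, high = min(low, point), max(high, point)
        family = r.family if low != high else Family.FIXED
        return ParameterRange(point, low, high, family)

    rr = {k: u(*rr_bounds) for k in (
        "rr_dis_dm_vs_sb", "rr_dis_dm_vs_bha", "rr_rev_dis_bha_vs_dm",
        "rr_rev_nondis_bha_vs_dm", "rr_rev_dis_dm_vs_sb", "rr_rev_nondis_dm_vs_sb")}
    probs = {}
    for a in AGE_BANDS:
        for stem in ("p_dis_sb", "p_rev_dis_sb", "p_rev_nondis_sb"):
            probs[f"{stem}_{a}"] = u(*prob_bounds)

    # worst-case inflation of any tabulated probability across strategies
    inflation = max(
        1.0,
        rr["rr_dis_dm_vs_sb"],
        rr["rr_dis_dm_vs_sb"] / rr["rr_dis_dm_vs_bha"],
        rr["rr_rev_dis_dm_vs_sb"],
        rr["rr_rev_dis_dm_vs_sb"] * rr["rr_rev_dis_bha_vs_dm"],
        rr["rr_rev_nondis_dm_vs_sb"],
        rr["rr_rev_nondis_dm_vs_sb"] * rr["rr_rev_nondis_bha_vs_dm"],
    )
    # three competing events per state; keep the worst sum comfortably < 1
    cap = 0.9 / (3.0 * inflation)
    scale = min(1.0, cap / max(probs.values()))
    probs = {k: v * scale for k, v in probs.items()}

    utils = {k: u(*utility_bounds) for k in ("u_well_bha", "u_well_sb", "u_well_dm")}
    disut = {k: u(*disutility_bounds) for k in ("d_dislocation", "d_r_tha", "d_rr_tha")}
    costs = {k: u(*cost_bounds) for k in (
        "c_dislocation_event", "c_implant_bha", "c_implant_sb", "c_implant_dm",
        "fee_bha", "fee_sb", "fee_dm", "fee_r_tha",
        "c_initial_bha", "c_initial_sb", "c_initial_dm", "c_well_annual")}

    ranges: dict[str, ParameterRange] = {}
    for k, v in probs.items():
        ranges[k] = clipped_range(v, "probability", 0.0, 1.0)
    for k, v in rr.items():
        ranges[k] = derive_range(v, "relative_risk")
    for k, v in utils.items():
        ranges[k] = clipped_range(v, "utility", 0.0, 1.0)
    for k, v in disut.items():
        ranges[k] = clipped_range(v, "disutility", -1.0, 0.0)
    for k, v in costs.items():
        ranges[k] = derive_range(v, "cost")
    # derived composite utilities: point values recomputed at resolve time
    from .parameters import composite_utilities

    u_r, u_rr = composite_utilities(utils["u_well_dm"], disut["d_r_tha"], disut["d_rr_tha"])
    for k, v in (("u_well_r_tha", float(u_r)), ("u_well_rr_tha", float(u_rr))):
        r = clipped_range(v, "utility", 0.0, 1.0)
        ranges[k] = ParameterRange(r.point, r.low, r.high, r.family, derived=True)
    return ParameterSet(ranges)
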