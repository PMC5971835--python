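"""Forward simulator of columns and commingled assemblages.

Generates vertebral columns with the statistical structure the analysis
assumes: annual growth lines whose spacing decreases toward the facet
periphery (saturating growth), rare per-facet miscounts biased toward one
line too few, occasional unscorable facets, and along-column centrum
length variation with a target coefficient of variation.  Assemblages
concatenate columns, discard vertebrae, strip articulation information,
and return a ground-truth table for recovery tests.

All randomness flows through one explicit numpy Generator; a fixed seed
fixes the full output stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .records import Condition, Side, VertebraRecord, ZygantralRecord

# Calibrated so a two-year individual puts its first line near 2/3 of
# zygantral length and its second close to the periphery, as observed in
# the extant reference colubrid.
DEFAULT_L0_FRAC = 0.1
DEFAULT_K_RATE = 0.7
POST_LINE_GROWTH_YEARS = 0.15


@dataclass(frozen=True)
class GrowthParams:
    """Saturating (von Bertalanffy form) zygantral growth.

    l0_frac: hatching length as a fraction of the asymptote, in (0, 1).
    k_rate:  growth-rate constant per year (> 0).
    age_years: age at death, whole years.
    """

    l0_frac: float = DEFAULT_L0_FRAC
    k_rate: float = DEFAULT_K_RATE
    age_years: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.l0_frac < 1.0):
            raise ValueError("l0_frac must be in (0, 1)")
        if self.k_rate <= 0:
            raise ValueError("k_rate must be > 0")
        if self.age_years < 0:
            raise ValueError("age_years must be >= 0")


@dataclass(frozen=True)
class ColumnNoise:
    """Observation noise along one column.

    miscount_prob: per-facet probability of recording one line fewer
        (faint peripheral lines are lost far more often than invented).
    overcount_prob: per-facet probability of one extra line.
    damage_prob: per-facet probability the record is unscorable.
    cl_cv_percent: target coefficient of variation (%) of centrum length
        across the column, combining the smooth positional size profile
        with measurement-scale noise.
    """

    miscount_prob: float = 0.03
    overcount_prob: float = 0.005
    damage_prob: float = 0.01
    cl_cv_percent: float = 12.7

    def __post_init__(self) -> None:
        for name in ("miscount_prob", "overcount_prob", "damage_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cl_cv_percent <= 0:
            raise ValueError("cl_cv_percent must be > 0")


@dataclass(frozen=True)
class IndividualConfig:
    age_years: int
    n_vertebrae: int
    mean_centrum_mm: float
    growth: GrowthParams = GrowthParams()
    noise: ColumnNoise = ColumnNoise()

    def __post_init__(self) -> None:
        if self.n_vertebrae < 1:
            raise ValueError("n_vertebrae must be >= 1")
        if self.mean_centrum_mm <= 0:
            raise ValueError("mean_centrum_mm must be > 0")


@dataclass(frozen=True)
class AssemblageConfig:
    individuals: tuple[IndividualConfig, ...]
    fragmentation_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fragmentation_prob <= 1.0):
            raise ValueError("fragmentation_prob must be in [0, 1]")


def growth_curve(p: GrowthParams, t: float) -> float:
    """Fraction of asymptotic zygantral length at age ``t`` years.

    L(t) = 1 - (1 - l0_frac) * exp(-k_rate * t): strictly increasing from
    l0_frac at hatching toward 1.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    return 1.0 - (1.0 - p.l0_frac) * math.exp(-p.k_rate * t)


def simulate_line_positions(p: GrowthParams,
                            post_line_growth: float = POST_LINE_GROWTH_YEARS
                            ) -> tuple[float, ...]:
    """Normalized positions of the annual lines on a finished facet.

    Line i sits where the facet edge stood at age i, normalized by the
    final length reached a fraction of a year after the last line (growth
    resumes briefly before death).  Spacings decrease strictly — younger
    growth is faster.
    """
    if p.age_years == 0:
        return ()
    final = growth_curve(p, p.age_years + post_line_growth)
    pos = [growth_curve(p, i) / final for i in range(1, p.age_years + 1)]
    # deep into saturation the exact values are distinct but can collide at
    # double precision; nudge by ulps so the strict ordering survives
    upper = 1.0
    for i in reversed(range(len(pos))):
        upper = np.nextafter(upper, 0.0)
        if pos[i] >= upper:
            pos[i] = upper
        upper = pos[i]
    return tuple(pos)


def _perturbed_positions(p: GrowthParams, count: int,
                         rng: np.random.Generator) -> Optional[tuple[float, ...]]:
    """Line positions adjusted to a miscounted/overcounted facet.

    A lost line is dropped uniformly at random; an extra line is inserted
    at the midpoint of a uniformly chosen gap.  Returns None for count 0.
    """
    base = list(simulate_line_positions(p))
    if count == len(base):
        pos = base
    elif count == len(base) - 1 and base:
        del base[rng.integers(len(base))]
        pos = base
    elif count == len(base) + 1 and base:
        gaps = [0.0] + base
        i = int(rng.integers(len(gaps) - 1))
        base.insert(i, (gaps[i] + gaps[i + 1]) / 2.0)
        pos = base
    else:
        return None
    return tuple(pos) if pos else None


def _hump_profile(n: int, target_cv: float) -> np.ndarray:
    """Smooth symmetric along-column size profile with a given CV.

    Centrum length peaks mid-column; the profile is 1 + a*sin(pi*x) with
    the amplitude solved by bisection so the realized (discrete) CV
    matches ``target_cv``.  Degenerate cases (n == 1 or unreachable
    targets) clamp rather than fail.
    """
    x = (np.arange(n) + 0.5) / n
    shape = np.sin(np.pi * x)
    if n == 1 or target_cv <= 0:
        return np.ones(n)

    def cv(a: float) -> float:
        prof = 1.0 + a * shape
        return prof.std() / prof.mean()

    lo, hi = 0.0, 50.0
    if cv(hi) < target_cv:
        return 1.0 + hi * shape
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if cv(mid) < target_cv:
            lo = mid
        else:
            hi = mid
    return 1.0 + hi * shape


# Fraction of centrum-length variance carried by the positional profile;
# the remainder is independent per-vertebra noise.
PROFILE_VARIANCE_SHARE = 0.7


def simulate_column(age_years: int, n_vertebrae: int, mean_centrum_mm: float,
                    growth: GrowthParams = None,
                    noise: ColumnNoise = ColumnNoise(),
                    rng: np.random.Generator = None,
                    individual_label: str = "ind0",
                    lot_id: str = "SIM") -> tuple[list[VertebraRecord], pd.DataFrame]:
    """Simulate one articulated column with ground-truth labels.

    Per facet, independently: the recorded count is the true age, one
    fewer with ``miscount_prob``, one more with ``overcount_prob``, or the
    facet is unscorable with ``damage_prob``.  Centrum lengths follow a
    mid-column hump profile plus noise targeting ``cl_cv_percent``.
    Returns the records and a truth table (record_id, individual_label,
    true_age, column_position).
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if growth is None:
        growth = GrowthParams(age_years=age_years)
    elif growth.age_years != age_years:
        raise ValueError("growth.age_years must match age_years")

    cv_total = noise.cl_cv_percent / 100.0
    cv_profile = cv_total * math.sqrt(PROFILE_VARIANCE_SHARE)
    profile = _hump_profile(n_vertebrae, cv_profile)
    tau = math.sqrt(max(cv_total ** 2 - (profile.std() / profile.mean()) ** 2, 0.0))
    lengths = profile / profile.mean() * mean_centrum_mm
    lengths = lengths * np.clip(1.0 + tau * rng.standard_normal(n_vertebrae), 0.05, None)

    records: list[VertebraRecord] = []
    truth_rows = []
    for i in range(n_vertebrae):
        zygs = {}
        for side in (Side.LEFT, Side.RIGHT):
            if rng.random() < noise.damage_prob:
                zygs[side] = ZygantralRecord(side=side, condition=Condition.DAMAGED)
                continue
            count = age_years
            u = rng.random()
            if u < noise.miscount_prob and age_years > 0:
                count = age_years - 1
            elif u < noise.miscount_prob + noise.overcount_prob:
                count = age_years + 1
            zygs[side] = ZygantralRecord(
                side=side, line_count=count,
                line_positions=_perturbed_positions(growth, count, rng),
                condition=Condition.INTACT)
        rid = f"{individual_label}-v{i + 1:03d}"
        records.append(VertebraRecord(
            record_id=rid, lot_id=lot_id, specimen_id=individual_label,
            column_position=i + 1,
            centrum_length_mm=float(lengths[i]),
            left=zygs[Side.LEFT], right=zygs[Side.RIGHT]))
        truth_rows.append((rid, individual_label, age_years, i + 1))
    truth = pd.DataFrame(truth_rows, columns=["record_id", "individual_label",
                                              "true_age", "column_position"])
    return records, truth


def simulate_assemblage(cfg: AssemblageConfig
                        ) -> tuple[list[VertebraRecord], pd.DataFrame]:
    """Simulate a commingled assemblage plus its ground truth.

    Columns are concatenated, each vertebra is independently discarded
    with ``fragmentation_prob``, and articulation evidence (column
    position, specimen identity) is stripped; record ids are anonymized
    and shuffled.  The truth table maps the anonymized ids back to
    individuals and true ages.
    """
    rng = np.random.default_rng(cfg.seed)
    all_records: list[VertebraRecord] = []
    truths: list[pd.DataFrame] = []
    for idx, ind in enumerate(cfg.individuals):
        recs, truth = simulate_column(
            ind.age_years, ind.n_vertebrae, ind.mean_centrum_mm,
            growth=GrowthParams(ind.growth.l0_frac, ind.growth.k_rate,
                                ind.age_years),
            noise=ind.noise, rng=rng,
            individual_label=f"ind{idx + 1}")
        all_records.extend(recs)
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True)

    keep = rng.random(len(all_records)) >= cfg.fragmentation_prob
    kept = [r for r, k in zip(all_records, keep) if k]
    truth = truth[keep].reset_index(drop=True)
    if not kept:
        import warnings
        warnings.warn("fragmentation discarded every vertebra; assemblage is empty")

    order = rng.permutation(len(kept))
    anonymized = []
    new_ids = []
    for new_idx, old_idx in enumerate(order):
        v = kept[old_idx]
        rid = f"V{new_idx + 1:04d}"
        new_ids.append((old_idx, rid))
        anonymized.append(VertebraRecord(
            record_id=rid, lot_id=v.lot_id, specimen_id=None,
            column_position=None, centrum_length_mm=v.centrum_length_mm,
            left=v.left, right=v.right))
    id_map = {old: rid for old, rid in new_ids}
    truth = truth.assign(record_id=[id_map[i] for i in range(len(kept))])
    truth = truth.drop(columns=["column_position"])
    truth = truth.set_index("record_id").loc[[r.record_id for r in anonymized]]
    return anonymized, truth.reset_index()


# ---------------------------------------------------------------------------
# Config file support

def load_assemblage_config(source) -> AssemblageConfig:
    """Read an AssemblageConfig from a YAML key-value file or stream."""
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return load_assemblage_config(fh)
    doc = yaml.safe_load(source)
    individuals = tuple(
        IndividualConfig(
            age_years=int(ind["age_years"]),
            n_vertebrae=int(ind["n_vertebrae"]),
            mean_centrum_mm=float(ind["mean_centrum_mm"]),
            growth=GrowthParams(age_years=int(ind["age_years"]),
                                **ind.get("growth", {})),
            noise=ColumnNoise(**ind.get("noise", {})),
        )
        for ind in doc["individuals"]
    )
    return AssemblageConfig(
        individuals=individuals,
        fragmentation_prob=float(doc.get("fragmentation_prob", 0.0)),
        seed=int(doc.get("seed", 0)),
    )
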