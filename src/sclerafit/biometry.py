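"""Ocular biometry from delineated OCT interfaces, plus shift / delta stats.

Works on long-format cohort tables with columns
``animal_id, eye, treatment, timepoint, age_days, outcome, value,
excluded, reason``.  Eye averaging precedes all group statistics: each
animal contributes the mean of its available (non-excluded) eyes at
each timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InterfaceSet",
    "BiometryRecord",
    "SEGMENT_NAMES",
    "optical_to_geometric",
    "derive_biometry",
    "eye_average",
    "shift",
    "delta_from_baseline",
    "apply_exclusions",
    "dose_from_pellet",
]

SEGMENT_NAMES = ("CCT", "ACD", "LT", "VCD", "RT")

_INTERFACES = (
    "anterior_cornea",
    "posterior_cornea",
    "anterior_lens",
    "posterior_lens",
    "vitreoretinal",
    "rpe",
)


@dataclass(frozen=True)
class InterfaceSet:
    """Optical-path positions (um) of the six axial interfaces of one A-scan."""

    anterior_cornea: float
    posterior_cornea: float
    anterior_lens: float
    posterior_lens: float
    vitreoretinal: float
    rpe: float

    def positions(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in _INTERFACES)

    def __post_init__(self) -> None:
        pos = self.positions()
        for (na, a), (nb, b) in zip(
            zip(_INTERFACES, pos), zip(_INTERFACES[1:], pos[1:])
        ):
            if b <= a:
                raise ValueError(
                    f"interfaces not strictly increasing: {na}={a} >= {nb}={b}"
                )


@dataclass
class BiometryRecord:
    """One eye x timepoint set of geometric measurements (um) + refraction (D)."""

    animal_id: str
    eye: str
    timepoint: str
    CCT: float
    ACD: float
    LT: float
    VCD: float
    RT: float
    AL: float
    RE: float = np.nan
    age_days: float = np.nan
    corneal_curvature: float = np.nan
    excluded: bool = False
    reason: str = ""


def optical_to_geometric(optical_path: float, refractive_index: float = 1.39):
    """Convert optical path length to physical distance (um / um).

    A single average refractive index (default 1.39) is applied to the
    whole A-scan.
    """
    if refractive_index <= 0:
        raise ValueError(f"refractive index must be positive, got {refractive_index}")
    path = np.asarray(optical_path, dtype=float)
    if np.any(path < 0):
        raise ValueError("optical path must be non-negative")
    out = path / refractive_index
    return float(out) if np.isscalar(optical_path) else out


def derive_biometry(
    interfaces: InterfaceSet,
    refraction: float = np.nan,
    *,
    animal_id: str = "",
    eye: str = "OD",
    timepoint: str = "t0",
    age_days: float = np.nan,
    refractive_index: float = 1.39,
) -> BiometryRecord:
    """Segment lengths from one interface set (geometric um).

    AL is the anterior-cornea-to-RPE distance and equals the sum of the
    five segments by construction.
    """
    geo = [optical_to_geometric(p, refractive_index) for p in interfaces.positions()]
    segments = dict(zip(SEGMENT_NAMES, np.diff(geo)))
    return BiometryRecord(
        animal_id=animal_id,
        eye=eye,
        timepoint=timepoint,
        RE=refraction,
        age_days=age_days,
        AL=geo[-1] - geo[0],
        **segments,
    )


def eye_average(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long-format table to one value per animal x timepoint x outcome.

    Excluded eyes are dropped first; an animal with no analyzable eye at
    a timepoint vanishes from that cell.
    """
    usable = table
    if "excluded" in table.columns:
        usable = table[~table["excluded"].astype(bool)]
    grouped = (
        usable.groupby(["treatment", "animal_id", "timepoint", "outcome"], sort=False)[
            "value"
        ]
        .mean()
        .reset_index()
    )
    return grouped


def shift(
    table: pd.DataFrame,
    outcome: str,
    timepoint: str,
    control_label: str = "Ctrl",
) -> pd.DataFrame:
    """Per-animal shift = eye-averaged value minus the control-group mean.

    The control group's mean shift is zero by construction.  Returns the
    per-animal table with a ``shift`` column.
    """
    avg = eye_average(table)
    cell = avg[(avg["outcome"] == outcome) & (avg["timepoint"] == timepoint)]
    if cell.empty:
        raise ValueError(f"no data for outcome {outcome!r} at timepoint {timepoint!r}")
    ctrl = cell[cell["treatment"] == control_label]
    if ctrl.empty:
        raise ValueError(f"control group {control_label!r} empty at {timepoint!r}")
    ref = ctrl["value"].mean()
    out = cell.copy()
    out["shift"] = out["value"] - ref
    return out


def delta_from_baseline(
    table: pd.DataFrame, outcome: str, baseline: str = "t0"
) -> pd.DataFrame:
    """Per-animal change from the animal's own baseline measurement.

    Animals lacking a baseline are excluded (reported in the ``dropped``
    attribute of the result frame's attrs).
    """
    avg = eye_average(table)
    data = avg[avg["outcome"] == outcome]
    base = data[data["timepoint"] == baseline].set_index("animal_id")["value"]
    out = data.copy()
    out["delta"] = out["value"] - out["animal_id"].map(base)
    dropped = sorted(set(out.loc[out["delta"].isna(), "animal_id"]))
    out = out.dropna(subset=["delta"])
    out.attrs["dropped"] = dropped
    return out


def apply_exclusions(
    table: pd.DataFrame, flagged: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict]:
    """Mark opacity-flagged eyes as excluded and report an audit log.

    ``flagged`` rows carry ``animal_id, eye`` (and optionally ``reason``);
    matching eyes are excluded at every timepoint.  The animal is kept
    as long as one eye remains.
    """
    out = table.copy()
    if "excluded" not in out.columns:
        out["excluded"] = False
    if "reason" not in out.columns:
        out["reason"] = ""
    if flagged is not None and not flagged.empty:
        for _, row in flagged.iterrows():
            m = (out["animal_id"] == row["animal_id"]) & (out["eye"] == row["eye"])
            out.loc[m, "excluded"] = True
            out.loc[m, "reason"] = row.get("reason", "opacity")
    eyes = out[["animal_id", "eye", "excluded"]].drop_duplicates()
    n_excluded = int(eyes["excluded"].sum())
    analyzable = eyes[~eyes["excluded"]]
    audit = {
        "n_eyes": int(len(eyes)),
        "n_excluded_eyes": n_excluded,
        "n_analyzable_eyes": int(len(analyzable)),
        "n_animals_retained": int(analyzable["animal_id"].nunique()),
        "n_animals_dropped": int(
            eyes["animal_id"].nunique() - analyzable["animal_id"].nunique()
        ),
    }
    return out, audit


def dose_from_pellet(pellet_rate: float, atRA_mass_fraction: float) -> float:
    """Dose in mg drug per kg body mass.

    ``pellet_rate`` is mg of pellet per g body mass and
    ``atRA_mass_fraction`` the drug fraction of the pellet by weight
    (e.g. 2.5 mg/g of a 1% pellet -> 25 mg/kg).
    """
    if pellet_rate < 0:
        raise ValueError("pellet_rate must be >= 0")
    if not 0 < atRA_mass_fraction <= 1:
        raise ValueError(
            f"mass fraction must lie in (0, 1], got {atRA_mass_fraction}"
        )
    return pellet_rate * atRA_mass_fraction * 1000.0
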