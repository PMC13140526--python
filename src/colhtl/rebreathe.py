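"""CO-rebreathing haematology: haemoglobin mass and intravascular volumes.

The CO-rebreathing method estimates total circulating haemoglobin mass
(Hb_mass) by dilution of a known CO bolus: the absorbed CO volume divided by
the rise in carboxyhaemoglobin saturation (ΔCOHb) gives the CO-binding
capacity of the circulation, which a binding constant (Hüfner-type, mL CO per
g Hb) converts to grams of haemoglobin.  Intravascular volumes follow from
Hb_mass, venous haemoglobin concentration and haematocrit via the whole-body
to venous haematocrit ratio (f-cell).

Both the 2-min and 6-min rebreathing protocols reduce to the same mass
balance; they differ only in how the unabsorbed CO (circuit remainder plus
exhaled) is accounted, which enters here as a single input field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HaemConstants",
    "RebreathingRecord",
    "HaemVolumes",
    "QCError",
    "hbmass_from_rebreathing",
    "derive_volumes",
    "typical_error",
]

#: ΔCOHb below this (percentage points) is rejected: the dilution quotient
#: becomes numerically unstable and the test is physiologically implausible.
DELTA_COHB_FLOOR = 0.5

#: Triplicate coefficient-of-variation bound used for QC flagging.
TRIPLICATE_CV_LIMIT = 5.0


class QCError(ValueError):
    """A rebreathing record failed a quality-control precondition."""


@dataclass(frozen=True)
class HaemConstants:
    """Physical constants of the CO dilution mass balance.

    Parameters
    ----------
    co_binding:
        CO-binding capacity of haemoglobin, mL CO (STPD) per g Hb.
        1.39 is the theoretical Hüfner value used by the optimized
        rebreathing method.
    fcell:
        Whole-body to venous haematocrit ratio used when converting
        Hb_mass to blood volume.
    """

    co_binding: float = 1.39
    fcell: float = 0.91

    def __post_init__(self) -> None:
        if not (1.30 <= self.co_binding <= 1.40):
            raise ValueError(f"co_binding {self.co_binding} outside [1.30, 1.40]")
        if not (0.85 <= self.fcell <= 1.0):
            raise ValueError(f"fcell {self.fcell} outside [0.85, 1.0]")


@dataclass
class RebreathingRecord:
    """Raw observations from one CO-rebreathing test.

    COHb and [Hb] fields are triplicate means; the triplicate CVs (in %)
    may be stored for QC and are checked against ``TRIPLICATE_CV_LIMIT``.
    """

    method: str  # "2min" or "6min"
    co_administered: float  # mL
    co_unabsorbed: float  # mL (circuit remainder + exhaled)
    cohb_pre: float  # %
    cohb_post: float  # %
    hb_conc: float  # g/L venous
    hct: float  # fraction 0-1
    triplicate_cv: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("2min", "6min"):
            raise ValueError(f"unknown rebreathing method {self.method!r}")
        if self.co_unabsorbed >= self.co_administered:
            raise QCError("unabsorbed CO must be below the administered volume")
        if self.co_administered - self.co_unabsorbed < 0:
            raise QCError("negative absorbed CO volume")
        for key, cv in self.triplicate_cv.items():
            if cv > TRIPLICATE_CV_LIMIT:
                raise QCError(
                    f"triplicate CV for {key} is {cv:.1f}% "
                    f"(limit {TRIPLICATE_CV_LIMIT}%)"
                )

    @property
    def delta_cohb(self) -> float:
        """Rise in COHb across the test, percentage points."""
        return self.cohb_post - self.cohb_pre

    @property
    def co_absorbed(self) -> float:
        """CO volume taken up by the circulation, mL."""
        return self.co_administered - self.co_unabsorbed


@dataclass(frozen=True)
class HaemVolumes:
    """Derived haematological volumes; BV = RBCV + PV holds by construction."""

    hbmass: float  # g
    hbmass_rel: float  # g/kg
    rbcv: float  # mL
    pv: float  # mL
    bv: float  # mL


def hbmass_from_rebreathing(
    record: RebreathingRecord, constants: HaemConstants = HaemConstants()
) -> float:
    """Haemoglobin mass (g) from the CO dilution mass balance.

    Hb_mass = absorbed CO [mL] x 100 / (ΔCOHb [%] x co_binding [mL/g]).

    Raises
    ------
    QCError
        If ΔCOHb is at or below the QC floor (``DELTA_COHB_FLOOR``
        percentage points) or the absorbed volume is non-positive.
    """
    d = record.delta_cohb
    if d <= DELTA_COHB_FLOOR:
        raise QCError(
            f"ΔCOHb = {d:.2f} points is at/below the QC floor of "
            f"{DELTA_COHB_FLOOR}; test invalid"
        )
    absorbed = record.co_absorbed
    if absorbed <= 0:
        raise QCError("non-positive absorbed CO volume")
    return absorbed * 100.0 / (d * constants.co_binding)


def derive_volumes(
    hbmass: float,
    hb_conc: float,
    hct: float,
    constants: HaemConstants = HaemConstants(),
    body_mass: float | None = None,
) -> HaemVolumes:
    """Blood, red-cell and plasma volumes from Hb_mass, [Hb] and HCT.

    BV [mL] = Hb_mass [g] / ([Hb] [g/L] x fcell) x 1000
    RBCV    = BV x HCT x fcell
    PV      = BV - RBCV

    ``hct`` is a fraction (0-1); a value above 1 almost certainly means
    percent was passed and is rejected.
    """
    if hbmass <= 0:
        raise ValueError("hbmass must be positive")
    if not (50.0 <= hb_conc <= 250.0):
        raise ValueError(f"[Hb] {hb_conc} g/L outside physiological range")
    if not (0.30 <= hct <= 0.60):
        raise ValueError(
            f"HCT {hct} outside [0.30, 0.60]; pass a fraction, not percent"
        )
    bv = hbmass / (hb_conc * constants.fcell) * 1000.0
    rbcv = bv * hct * constants.fcell
    pv = bv - rbcv
    rel = hbmass / body_mass if body_mass else math.nan
    return HaemVolumes(hbmass=hbmass, hbmass_rel=rel, rbcv=rbcv, pv=pv, bv=bv)


def typical_error(duplicates) -> tuple[float, float]:
    """Duplicate-measurement reliability.

    Parameters
    ----------
    duplicates:
        Sequence of (first, second) measurement pairs.

    Returns
    -------
    (mean_pct_diff, te):
        Mean absolute percent difference between duplicates, and the
        typical error: the SD of the duplicate differences divided by √2,
        in the units of the measurements.
    """
    pairs = np.asarray(duplicates, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need at least 2 duplicate pairs of shape (n, 2)")
    diffs = pairs[:, 1] - pairs[:, 0]
    te = float(np.std(diffs, ddof=1) / math.sqrt(2.0))
    means = pairs.mean(axis=1)
    mean_pct = float(np.mean(np.abs(diffs) / means) * 100.0)
    return mean_pct, te
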