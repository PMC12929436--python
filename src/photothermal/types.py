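"""Core domain types for photoperiod-response experiments.

The experiment these types describe: spring barley genotypes grown in
controlled-environment tents under a ladder of photoperiods (hours of light
per 24 h day), with flowering recorded as accumulated thermal time
(growing degree-days, base 0 °C) from emergence to heading (awn emergence,
BBCH 49).  Two genetic groups are modelled: four recombinant inbred lines
from the HEB-25 nested association mapping population carrying the factorial
allele combinations at *ELF3* and *PPD-H1*, and the Bowman cultivar with two
of its near-isogenic introgression lines (*elf3* mutant and *PhyC-e*).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Elf3Allele",
    "PpdH1Allele",
    "PhyCAllele",
    "GenotypeSpec",
    "PlantRecord",
    "TemperatureLog",
    "ResponseParams",
    "CtRecord",
    "CANONICAL_GENOTYPES",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a record or table violates a domain invariant."""


class Group(str, enum.Enum):
    HEB = "HEB"
    BOWMAN = "Bowman"


class Elf3Allele(str, enum.Enum):
    #: domesticated allele (H. vulgare)
    HV = "Hv"
    #: wild allele (H. spontaneum)
    HSP = "Hsp"
    #: loss-of-function mutant (eam8-type), photoperiod-insensitive early
    ELF3_MUTANT = "elf3"


class PpdH1Allele(str, enum.Enum):
    #: recessive ppd-H1 — photoperiod-responsive up to a ~20 h threshold
    HV = "Hv"
    #: dominant Ppd-H1 — threshold already saturated at 16 h, flat response
    HSP = "Hsp"


class PhyCAllele(str, enum.Enum):
    PHYC_I = "PhyC-I"
    PHYC_E = "PhyC-e"


@dataclass(frozen=True)
class GenotypeSpec:
    """A genotype's allelic make-up at the three flowering-time loci.

    Bowman-group lines all sit in the recessive *ppd-H1* background and
    differ only at *ELF3* or *PHYC*; that invariant is enforced here.
    """

    id: str
    group: Group
    elf3_allele: Elf3Allele
    ppdh1_allele: PpdH1Allele
    phyc_allele: PhyCAllele = PhyCAllele.PHYC_I

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("genotype id must be non-empty")
        if self.group == Group.BOWMAN and self.ppdh1_allele != PpdH1Allele.HV:
            raise ValidationError(
                f"Bowman-group genotype {self.id!r} must carry the recessive "
                "ppd-H1 (Hv) allele"
            )


def _canonical() -> dict[str, GenotypeSpec]:
    heb = [
        ("ELF3_Hv/PPD-H1_Hv", Elf3Allele.HV, PpdH1Allele.HV),
        ("ELF3_Hv/PPD-H1_Hsp", Elf3Allele.HV, PpdH1Allele.HSP),
        ("ELF3_Hsp/PPD-H1_Hv", Elf3Allele.HSP, PpdH1Allele.HV),
        ("ELF3_Hsp/PPD-H1_Hsp", Elf3Allele.HSP, PpdH1Allele.HSP),
    ]
    out = {
        name: GenotypeSpec(name, Group.HEB, elf3, ppdh1)
        for name, elf3, ppdh1 in heb
    }
    out["BW_WT"] = GenotypeSpec(
        "BW_WT", Group.BOWMAN, Elf3Allele.HSP, PpdH1Allele.HV, PhyCAllele.PHYC_I
    )
    out["BW_ELF3"] = GenotypeSpec(
        "BW_ELF3", Group.BOWMAN, Elf3Allele.ELF3_MUTANT, PpdH1Allele.HV,
        PhyCAllele.PHYC_I,
    )
    out["BW_PHYC"] = GenotypeSpec(
        "BW_PHYC", Group.BOWMAN, Elf3Allele.HSP, PpdH1Allele.HV,
        PhyCAllele.PHYC_E,
    )
    return out


#: The seven genotypes of the reference experiment, keyed by id.
CANONICAL_GENOTYPES: dict[str, GenotypeSpec] = _canonical()


@dataclass(frozen=True)
class PlantRecord:
    """One plant's outcome: genotype, treatment, and thermal time to heading.

    ``thermal_time_cd`` (°Cd above base 0 °C, emergence → heading) is the
    response variable of every downstream analysis and is mandatory;
    ``days_to_heading`` is optional raw bookkeeping.
    """

    genotype: str
    photoperiod_h: float
    replicate: int
    repetition: int
    thermal_time_cd: float
    days_to_heading: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.photoperiod_h <= 24.0):
            raise ValidationError(
                f"photoperiod_h must be in [0, 24], got {self.photoperiod_h}"
            )
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")
        if self.repetition < 1:
            raise ValidationError("repetition must be a positive integer")
        if not math.isfinite(self.thermal_time_cd) or self.thermal_time_cd < 0:
            raise ValidationError(
                f"thermal_time_cd must be finite and >= 0, got "
                f"{self.thermal_time_cd}"
            )
        if self.days_to_heading is not None and self.days_to_heading < 0:
            raise ValidationError("days_to_heading must be >= 0")

    @property
    def dark_hours(self) -> float:
        return 24.0 - self.photoperiod_h


@dataclass
class TemperatureLog:
    """Timestamped air-temperature series (default cadence 30 min).

    Wraps a pandas Series with a DatetimeIndex; timestamps must be strictly
    increasing and temperatures finite.
    """

    series: pd.Series
    cadence: pd.Timedelta = pd.Timedelta(minutes=30)

    def __post_init__(self) -> None:
        if not isinstance(self.series.index, pd.DatetimeIndex):
            raise ValidationError("TemperatureLog requires a DatetimeIndex")
        if len(self.series) == 0:
            raise ValidationError("TemperatureLog must contain readings")
        if not self.series.index.is_monotonic_increasing or self.series.index.has_duplicates:
            raise ValidationError("timestamps must be strictly increasing")
        if not np.isfinite(self.series.to_numpy(dtype=float)).all():
            raise ValidationError("temperatures must be finite")

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[Tuple[object, float]],
        cadence: pd.Timedelta = pd.Timedelta(minutes=30),
    ) -> "TemperatureLog":
        times, temps = zip(*entries)
        return cls(
            pd.Series(list(temps), index=pd.DatetimeIndex(times), name="temp_c"),
            cadence=cadence,
        )

    @property
    def start(self) -> pd.Timestamp:
        return self.series.index[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.series.index[-1]

    def __len__(self) -> int:
        return len(self.series)


@dataclass(frozen=True)
class ResponseParams:
    """Parameters of the bi-linear (linear-plateau) photoperiod response.

    The genotype mean thermal time to heading at photoperiod P is

        mu(P) = I + S * max(0, T - P)

    i.e. a linear decline of slope -S (°Cd per hour of daylength) up to the
    threshold photoperiod T, then a plateau at the intrinsic earliness I —
    the minimum flowering time once the photoperiod requirement is saturated.

    ``sigma`` is the residual SD of individual plants around the genotype
    mean; sigma = 0 denotes a degenerate noise-free configuration (used by
    deterministic simulations).
    """

    intrinsic_earliness: float
    sensitivity: float
    threshold: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.intrinsic_earliness <= 0:
            raise ValidationError("intrinsic_earliness must be > 0 °Cd")
        if self.sensitivity < 0:
            raise ValidationError("sensitivity must be >= 0 °Cd/h")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0 °Cd")

    def mean(self, photoperiod_h: float) -> float:
        """Predicted mean thermal time (°Cd) at the given photoperiod."""
        return self.intrinsic_earliness + self.sensitivity * max(
            0.0, self.threshold - photoperiod_h
        )


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: a Ct value or an undetected flag.

    Technical replicates nest within biological replicates; ``zt`` is
    Zeitgeber Time, hours after lights-on, on the sampling day.
    """

    gene: str
    genotype: str
    photoperiod_h: float
    zt: float
    bio_rep: int
    tech_rep: int
    ct: Optional[float] = None
    undetected: bool = False

    def __post_init__(self) -> None:
        if self.undetected and self.ct is not None:
            raise ValidationError("undetected wells must not carry a Ct value")
        if not self.undetected:
            if self.ct is None:
                raise ValidationError("detected wells require a Ct value")
            if not (self.ct > 0 and math.isfinite(self.ct)):
                raise ValidationError(f"Ct must be finite and > 0, got {self.ct}")
        if not (0.0 <= self.photoperiod_h <= 24.0):
            raise ValidationError("photoperiod_h must be in [0, 24]")
        if self.bio_rep < 1 or self.tech_rep < 1:
            raise ValidationError("replicate indices must be positive")
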