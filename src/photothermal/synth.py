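"""Synthetic-data generators mirroring the growth-tent experiment.

The default design reproduces the reference layout: 7 genotypes (four HEB
allele combinations at *ELF3* x *PPD-H1*, plus Bowman wild type and its
*elf3* and *PhyC-e* introgression lines), five photoperiods
(16/18/20/22/24 h), five replicates and two experiment repetitions at a
constant 20 °C, i.e. 350 plant records.

Plant-level thermal time is drawn as

    y = I + S * max(0, T - P) + shift * 1[repetition = 2] + eps,
    eps ~ Normal(0, sigma^2),

truncated below at 1 °Cd so extreme noise draws cannot produce
non-physical flowering times.  The shipped per-genotype parameters are an
illustrative fixture qualitatively matching the reference phenotypes
(*ppd-H1* lines responsive with a 20 h threshold, *Ppd-H1* lines flat,
wild *ELF3* lowering intrinsic earliness, *PhyC-e* lowering sensitivity,
the *elf3* mutant flat and earliest); they are stated assumptions, not
measured values — in particular sigma = 12 °Cd, as no residual variance is
reported for the real experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    CANONICAL_GENOTYPES,
    CtRecord,
    GenotypeSpec,
    PlantRecord,
    ResponseParams,
    TemperatureLog,
    ValidationError,
)

__all__ = [
    "DesignSpec",
    "CtEffect",
    "DEFAULT_GENOTYPE_PARAMS",
    "default_design",
    "generate_phenotypes",
    "generate_temperature_log",
    "generate_ct_table",
    "default_ct_effects",
]

#: Illustrative generating parameters (I °Cd, S °Cd/h, T h, sigma °Cd).
DEFAULT_GENOTYPE_PARAMS: dict[str, ResponseParams] = {
    # HEB group: response driven by PPD-H1, earliness shifted by ELF3
    "ELF3_Hv/PPD-H1_Hv": ResponseParams(620.0, 55.0, 20.0, 12.0),
    "ELF3_Hsp/PPD-H1_Hv": ResponseParams(540.0, 55.0, 20.0, 12.0),
    "ELF3_Hv/PPD-H1_Hsp": ResponseParams(500.0, 0.0, 16.0, 12.0),
    "ELF3_Hsp/PPD-H1_Hsp": ResponseParams(460.0, 0.0, 16.0, 12.0),
    # Bowman group: PhyC-e halves sensitivity, elf3 mutant is flat-early
    "BW_WT": ResponseParams(600.0, 50.0, 20.0, 12.0),
    "BW_PHYC": ResponseParams(600.0, 25.0, 20.0, 12.0),
    "BW_ELF3": ResponseParams(420.0, 0.0, 16.0, 12.0),
}


@dataclass
class DesignSpec:
    """Layout of a simulated photoperiod experiment."""

    genotypes: Sequence[Tuple[GenotypeSpec, ResponseParams]]
    photoperiods_h: Sequence[float] = (16.0, 18.0, 20.0, 22.0, 24.0)
    replicates: int = 5
    repetitions: int = 2
    seed: int = 0
    #: additive °Cd offset applied to every plant of repetition 2
    repetition_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")
        if any(not (0.0 <= p <= 24.0) for p in self.photoperiods_h):
            raise ValidationError("photoperiods must lie in [0, 24]")
        if len(self.genotypes) == 0:
            raise ValidationError("at least one genotype is required")

    @property
    def n_records(self) -> int:
        return (
            len(self.genotypes)
            * len(self.photoperiods_h)
            * self.replicates
            * self.repetitions
        )


def default_design(seed: int = 0, **overrides) -> DesignSpec:
    """The reference 7-genotype design with the shipped fixture parameters."""
    genotypes = [
        (CANONICAL_GENOTYPES[gid], DEFAULT_GENOTYPE_PARAMS[gid])
        for gid in DEFAULT_GENOTYPE_PARAMS
    ]
    return DesignSpec(genotypes=genotypes, seed=seed, **overrides)


def generate_phenotypes(design: DesignSpec) -> list[PlantRecord]:
    """Draw plant records under the bi-linear means of the design.

    Reproducible for a given ``design.seed``; record order is the fixed
    nesting genotype > photoperiod > repetition > replicate.
    """
    for _, params in design.genotypes:
        if params.sigma < 0:
            raise ValidationError("sigma must be >= 0")
    rng = np.random.default_rng(design.seed)
    records: list[PlantRecord] = []
    for spec, params in design.genotypes:
        for p in design.photoperiods_h:
            mu = params.mean(p)
            for rep in range(1, design.repetitions + 1):
                shift = design.repetition_shift if rep == 2 else 0.0
                noise = rng.normal(0.0, params.sigma, design.replicates)
                for r in range(1, design.replicates + 1):
                    y = max(1.0, mu + shift + noise[r - 1])
                    records.append(
                        PlantRecord(
                            genotype=spec.id,
                            photoperiod_h=float(p),
                            replicate=r,
                            repetition=rep,
                            thermal_time_cd=float(y),
                        )
                    )
    return records


def generate_temperature_log(
    days: int,
    mean_c: float = 20.0,
    sd_c: float = 0.0,
    cadence_min: int = 30,
    seed: int = 0,
    start: str = "2023-03-01T00:00:00",
) -> TemperatureLog:
    """Simulate a datalogger trace: Normal(mean_c, sd_c^2) per reading."""
    if days < 1:
        raise ValidationError("days must be >= 1")
    if sd_c < 0:
        raise ValidationError("sd_c must be >= 0")
    per_day = (24 * 60) // cadence_min
    n = days * per_day
    rng = np.random.default_rng(seed)
    temps = rng.normal(mean_c, sd_c, n) if sd_c > 0 else np.full(n, mean_c)
    idx = pd.date_range(start=start, periods=n, freq=f"{cadence_min}min")
    return TemperatureLog(
        pd.Series(temps, index=idx, name="temp_c"),
        cadence=pd.Timedelta(minutes=cadence_min),
    )


def default_ct_effects() -> Tuple[
    list[str], list[str], list[float],
    dict[Tuple[str, str, float, float], "CtEffect"],
]:
    """Illustrative qPCR ground truth for the HEB expression comparison.

    Targets *PPD-H1* and *FT1* with *HvTubA* as reference, four HEB
    genotypes, contrasting 16 h and 22 h photoperiods, ZT 5/11/17/23.
    Lines carrying the dominant *Ppd-H1* (Hsp) allele express both genes
    more strongly; *PPD-H1* in recessive lines drops out half the time at
    ZT23 (lights off) and *FT1* is prone to dropout in the latest-flowering
    line at 16 h — mirroring the detection pattern of the real assay.
    Means are stated assumptions, not measured values.
    """
    genes = ["HvTubA", "PPD-H1", "FT1"]
    genotypes = [
        "ELF3_Hv/PPD-H1_Hv", "ELF3_Hv/PPD-H1_Hsp",
        "ELF3_Hsp/PPD-H1_Hv", "ELF3_Hsp/PPD-H1_Hsp",
    ]
    photoperiods = [16.0, 22.0]
    zts = [5.0, 11.0, 17.0, 23.0]
    effects: dict[Tuple[str, str, float, float], CtEffect] = {}
    for geno in genotypes:
        hsp = "PPD-H1_Hsp" in geno
        elf3_hsp = geno.startswith("ELF3_Hsp")
        for p in photoperiods:
            for zt in zts:
                effects[("HvTubA", geno, p, zt)] = CtEffect(22.0)
                # PPD-H1: ~3 cycles lower Ct (8x expression) in Hsp lines
                # at ZT11/17/23; recessive lines drop out at lights-off
                ppd = 27.0 if zt == 5.0 else (24.5 if hsp else 27.5)
                drop = 0.5 if (not hsp and zt == 23.0) else 0.0
                effects[("PPD-H1", geno, p, zt)] = CtEffect(ppd, drop)
                # FT1 tracks PPD-H1 output; wild ELF3 boosts it at ZT17/16h
                ft = 26.0 if hsp else 29.5
                if not hsp and elf3_hsp and zt == 17.0 and p == 16.0:
                    ft = 27.5
                ft_drop = 0.5 if (
                    geno == "ELF3_Hv/PPD-H1_Hv" and p == 16.0
                    and zt in (5.0, 11.0, 23.0)
                ) else 0.0
                effects[("FT1", geno, p, zt)] = CtEffect(ft, ft_drop)
    return genes, genotypes, photoperiods, effects


@dataclass(frozen=True)
class CtEffect:
    """True mean Ct and dropout probability for one assay cell."""

    mean_ct: float
    undetected_p: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.undetected_p <= 1.0):
            raise ValidationError("undetected_p must lie in [0, 1]")


def generate_ct_table(
    genes: Sequence[str],
    genotypes: Sequence[str],
    photoperiods: Sequence[float],
    effects: Mapping[Tuple[str, str, float, float], CtEffect],
    zts: Sequence[float] = (5.0, 11.0, 17.0, 23.0),
    bio_reps: int = 2,
    tech_reps: int = 2,
    bio_sd: float = 0.3,
    tech_sd: float = 0.15,
    seed: int = 0,
) -> list[CtRecord]:
    """Simulate a qPCR plate layout with nested bio/tech variance components.

    ``effects`` maps (gene, genotype, photoperiod, zt) to the cell's true
    mean Ct and per-well dropout probability; each well is independently
    flagged undetected with that probability, mirroring assays where a
    transcript falls below the detection floor in a subset of samples.
    """
    rng = np.random.default_rng(seed)
    records: list[CtRecord] = []
    for gene in genes:
        for geno in genotypes:
            for p in photoperiods:
                for zt in zts:
                    eff = effects[(gene, geno, float(p), float(zt))]
                    for b in range(1, bio_reps + 1):
                        bio_offset = rng.normal(0.0, bio_sd) if bio_sd > 0 else 0.0
                        for t in range(1, tech_reps + 1):
                            undet = bool(rng.random() < eff.undetected_p)
                            tech_noise = (
                                rng.normal(0.0, tech_sd) if tech_sd > 0 else 0.0
                            )
                            ct = None if undet else float(
                                eff.mean_ct + bio_offset + tech_noise
                            )
                            records.append(
                                CtRecord(
                                    gene=gene,
                                    genotype=geno,
                                    photoperiod_h=float(p),
                                    zt=float(zt),
                                    bio_rep=b,
                                    tech_rep=t,
                                    ct=ct,
                                    undetected=undet,
                                )
                            )
    return records
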