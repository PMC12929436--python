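# photothermal

Bi-linear photoperiod-response modelling for barley flowering-time
experiments, with pairwise treatment contrasts, delta-Ct qPCR expression
analysis, and a speed-breeding lighting energy/cost ledger.

## Who this is for

Speed breeding grows long-day cereals under extended photoperiods
(conventionally 22 h light / 2 h dark) to squeeze more generations into a
year — at a substantial lighting-energy cost.  How much light a genotype
actually *needs* depends on its alleles at the major flowering-time loci
(*PPD-H1*, *ELF3*, *PHYC*).  This package is for crop physiologists and
breeding-programme engineers who measure flowering time (as thermal time
to heading, °Cd) across a ladder of photoperiods and want to:

1. estimate each genotype's photoperiod-response parameters,
2. decide which genotypes are responsive vs already saturated,
3. derive a genotype-tailored speed-breeding photoperiod, and
4. put a kWh and currency figure on the resulting lighting savings.

## The model

Mean thermal time from emergence to heading at photoperiod *P* follows a
linear-plateau (hinge) response:

    mu(P) = I + S · max(0, T − P)

* **T** — threshold photoperiod (h): the breakpoint beyond which longer
  days no longer accelerate flowering;
* **S** — photoperiod sensitivity (°Cd/h): slope of the declining arm;
* **I** — intrinsic earliness (°Cd): the plateau, the minimum flowering
  time once the photoperiod requirement is saturated.

Plants scatter Gaussian (SD σ) around the genotype mean.  Fitting is
deterministic maximum likelihood (profiled least squares over a threshold
grid with local refinement); model variants share or drop parameters
across genotypes (e.g. a flat variant with S = 0) and are ranked by BIC.
See `docs/methods.md` for estimation details, identifiability handling,
and every default.

## Worked example

Simulate the reference experiment layout (7 genotypes — four HEB
*ELF3* × *PPD-H1* allele combinations plus Bowman wild type and its
*elf3* and *PhyC-e* introgression lines — at 16/18/20/22/24 h, five
replicates, two repetitions, 20 °C), fit per-genotype models, classify,
and recommend photoperiods:

```python
from photothermal import (default_design, generate_phenotypes,
                          select_best_per_genotype, classify_response,
                          recommend_photoperiod)

records = generate_phenotypes(default_design(seed=42))   # 350 plants
per_geno = select_best_per_genotype(records)             # BIC: flat vs full
classes = {}
for geno, best in per_geno.items():
    classes.update(classify_response(best, (16.0, 24.0)))
for geno in sorted(per_geno):
    est = per_geno[geno].estimates[geno].params
    rec = recommend_photoperiod(geno, classes, per_geno)
    print(geno, per_geno[geno].variant.name, round(est.intrinsic_earliness, 1),
          round(est.sensitivity, 2), classes[geno].category.value,
          rec.photoperiod_h)
```

Output (seed 42):

```
genotype                 variant       I      S      T class           rec P
BW_ELF3                  flat      421.6   0.00   n.i. flat_saturated     16
BW_PHYC                  full      597.4  24.00  20.26 responsive         20
BW_WT                    full      596.0  48.33  20.16 responsive         20
ELF3_Hsp/PPD-H1_Hsp      flat      460.4   0.00   n.i. flat_saturated     16
ELF3_Hsp/PPD-H1_Hv       full      535.7  55.39  20.04 responsive         20
ELF3_Hv/PPD-H1_Hsp       flat      499.4   0.00   n.i. flat_saturated     16
ELF3_Hv/PPD-H1_Hv        full      622.4  53.64  20.01 responsive         20
```

Reading it: genotypes carrying the recessive *ppd-H1* allele decline
until a ~20 h breakpoint (T ≈ 20, S ≈ 25–55 °Cd/h) and are recommended a
20 h speed-breeding photoperiod; lines with dominant *Ppd-H1* (and the
*elf3* mutant) are flat over the whole 16–24 h range — their threshold,
if any, lies below 16 h ("n.i." = not identifiable from this design) —
so the shortest tested photoperiod, 16 h, already saturates them.
*PhyC-e* (BW_PHYC vs BW_WT) halves sensitivity without moving the
plateau; wild *ELF3* (ELF3_Hsp rows) lowers intrinsic earliness.

What the shorter photoperiods are worth, against the 22 h standard:

```python
from photothermal import EnergyScenario, energy_report
energy_report(EnergyScenario(20.0, facility_area_sqft=10000.0))
```

```
fractional_saving_pct                          9
annual_fixture_saving_kwh                  474.5   (reported 475)
facility_cost_saving                    130487.5   (reported £130,000/yr)
```

A 22→20 h cut saves 9% of daily lighting — 475 kWh/yr per 0.65 kW,
8 sq ft fixture — about £130,000/yr for a 10,000 sq ft facility at
£0.22/kWh; a 22→16 h cut (flat genotypes) saves 27% and 1,423.5 kWh/yr
per fixture.

The same flow is available from the shell:

```bash
photothermal run --seed 42 --out results/        # full pipeline + report.md
photothermal simulate --out results/ --seed 42
photothermal fit --phenotypes results/phenotypes.csv --out fit.json
photothermal contrasts --phenotypes results/phenotypes.csv --pairs 16:20,20:22
photothermal energy --reduced 20 --facility-sqft 10000
```

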