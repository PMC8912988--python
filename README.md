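# afom

Excitation–emission matrix (EEM) processing and per-cell fluorescence
analysis for laboratory studies of microbially produced aquatic
fluorescent organic matter (AFOM).

## The problem

Bacteria growing in fresh water produce fluorescent dissolved organic
matter whose signatures fall in conventional "Coble peak" regions:
protein-like Peak T (λ_ex/λ_em 275/340 nm) and humic-like Peaks C
(340/420–470 nm) and C+ (400/470–505 nm). Quantifying how much of each
peak a culture produces — and how much *per cell* — requires a chain of
standard corrections on the raw instrument EEMs, plus coupling to
viable-count growth curves. This package implements that chain for a
six-condition simulated-freshwater (SFW) experiment crossing two nutrient
regimes (low: 0.3 mg L⁻¹ NO₃⁻ / 0 mg L⁻¹ PO₄³⁻; high: 50 / 0.1 mg L⁻¹)
with three glucose-DOC doses (0, 5, 800 mg L⁻¹), labelled SFW0–SFW5.

The computations, in pipeline order:

1. **Inner-filter correction** (absorbance/ABA method): each cell is
   multiplied by `10^(L·(A(λ_ex)+A(λ_em))/2)` with `A` the 1 cm
   absorbance and `L` the cuvette pathlength.
2. **Blank subtraction** against a fresh-matrix blank (after IFE, so the
   sample's attenuation does not bias the difference).
3. **Rayleigh scatter masking**: cells with `|λ_em − λ_ex| ≤ 10 nm`
   (first order) or `|λ_em − 2λ_ex| ≤ 10 nm` (second order) are masked.
4. **Cropping** to the UV–visible analysis window, excitation 240–490 nm
   and emission 250–500 nm.
5. **Quinine sulfate normalization**: intensities divided by the response
   of a 1 µg L⁻¹ quinine sulfate standard at 347.5/450 nm, giving QSU.
6. **Peak picking**: the emission cross-section at each peak's excitation
   wavelength, averaged over its emission band (point peaks read the
   nearest pixel).
7. **Growth coupling**: plate counts → CFU ml⁻¹, lag/exponential/
   stationary phase classification by log₁₀-slope thresholds, and
   enumeration-corrected fluorescence `f_QSU/CFU = QSU/(CFU ml⁻¹/10⁶)`.
8. **Summary tables**: per-condition 48 h endpoint intensities
   (mean ± sample SD) and the fraction table — each peak's maximal
   replicate-mean `f`, their sum `f_total`, and integer percent shares.

A forward simulator (`afom.synth`) generates every input — separable
Gaussian fluorophores with growth-linked amplitude kinetics, scatter
ridges, inner-filter attenuation, detector noise, and three-phase growth
from a 10⁵ CFU ml⁻¹ inoculum — with a ground-truth manifest, so the whole
pipeline is testable end to end without instrument data.

## Worked example

The fraction-table arithmetic on the reference per-cell fluorescence
values for the six conditions (`examples/percell_reference.csv`):

```sh
python analysis/05_fraction_worked_example.py
```

prints

```
              f_T  percent_T    f_C  percent_C  f_Cplus  percent_Cplus  f_total
condition
SFW0         50.2          8  128.6         20    462.2             72    641.0
SFW1        152.6         50   66.8         22     88.1             29    307.5
SFW2        391.8         40  346.5         36    237.0             24    975.3
SFW3        647.7         47  251.8         18    465.9             34   1365.4
SFW4       1346.3         51  693.2         26    623.2             23   2662.7
SFW5        229.7         10  929.6         42   1069.3             48   2228.6
```

Reading SFW2 (low nutrient, 5 mg L⁻¹ DOC): the three peaks contribute
391.8, 346.5 and 237.0 QSU per 10⁶ CFU, summing to `f_total` = 975.3,
split 40 % / 36 % / 24 % — protein-like Peak T dominates when carbon is
limited. Under excess DOC with high nutrients (SFW5) the humic-like peaks
C/C+ take 90 % of the total instead.

The full synthetic study runs through the numbered drivers:

```sh
python analysis/01_simulate_dataset.py --seed 1   # scratch/dataset
python analysis/02_preprocess_eems.py             # scratch/corrected
python analysis/03_condition_tables.py            # results/tables + truth check
python analysis/04_growth_phase_validation.py     # results/growth_phases.tsv
```

Driver 03 reports the recovered fraction tables against the generator's
manifest (worst per-peak `f` error ≈ 3 % with noise on); driver 04 finds
the exponential phase at 6–12 h in all 18 replicate curves and recovers
simulated change points within one sampling interval in ≈100 of 100
randomized curves.

There is also a CLI over the same functions:

```sh
afom synth --out scratch/dataset --seed 1
afom preprocess --dataset scratch/dataset --out scratch/corrected
afom analyze --corrected scratch/corrected --out results/tables
```

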