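# aacsia

Amino-acid compound-specific stable isotope analysis (AA-CSIA) for
trophic ecology, built around the coral–Symbiodiniaceae symbiosis but
applicable to any consumer/producer system measured at the amino-acid
level.

Bulk-tissue δ¹³C and δ¹⁵N values confound diet, baseline isotope
variation and tissue composition. Amino-acid-level measurements
disentangle them: *essential* amino-acid δ¹³C passes from diet to
consumer nearly unfractionated (a carbon "fingerprint" of the food
source), while *trophic* amino acids enrich in ¹⁵N with each trophic
transfer and *source* amino acids do not. This package implements the
standard analysis chain on such data:

* **Trophic position** from the glutamic acid–phenylalanine δ¹⁵N spacing

  TP<sub>Glx–Phe</sub> = (δ¹⁵N<sub>Glx</sub> − δ¹⁵N<sub>Phe</sub> − β)/Δ + 1,

  with producer offset β = 3.4 ‰ and trophic enrichment Δ = 7.6 ‰ by
  default, and first-order error propagation
  σ(TP) = √(σ²<sub>Glx</sub> + σ²<sub>Phe</sub> + σ²<sub>β</sub> + ((TP−1)σ<sub>Δ</sub>)²)/Δ.
* **Percent heterotrophy** from a linear two-end-member mixing model on
  TP, f = (TP<sub>mix</sub> − TP<sub>auto</sub>)/(TP<sub>het</sub> − TP<sub>auto</sub>),
  with the Phillips–Gregg first-order variance, under named end-member
  scenarios (detritivory, TP<sub>het</sub> = 2; zooplanktivory, TP<sub>het</sub> = 3).
* **∑V**, the mean absolute deviation of trophic-amino-acid δ¹⁵N within
  a sample — a proxy for heterotrophic microbial resynthesis of amino
  acids — and the inverse-variance **weighted mean** δ¹⁵N of trophic and
  source amino acids.
* **Multivariate fingerprinting**: mean-normalization of essential-δ¹³C
  panels, correlation-matrix PCA with significant correlation vectors
  and SD ellipses, Euclidean-distance PERMANOVA with sequential (Type I)
  sums of squares and permutation p-values, and linear discriminant
  classification (R/MASS scaling convention) with leave-one-out
  cross-validation and posterior assignment of consumers to autotrophic
  vs heterotrophic nutrition sources.
* A **synthetic-data generator** that emulates the isotope structure of
  a host/symbiont/plankton feeding experiment (producer-like Glx–Phe
  spacing in coral tissues, consumer-like spacing in plankton,
  amino-acid-specific plankton δ¹³C offsets averaging −5.5 ‰, +2.5 ‰
  δ¹⁵N offsets, triplicate analytical noise), with the exact latent
  ground truth serialized next to every dataset.

## Worked example

```python
from aacsia import (paper_preset, generate_dataset, tp_table,
                    heterotrophy_fraction, sum_v)

config = paper_preset(n_plankton=6)
table, truth = generate_dataset(config, seed=1)

tps = tp_table(table)
print(tps.groupby("fraction")[["tp", "tp_sd"]].mean().round(3))
#              tp  tp_sd
# fraction
# host      1.016  0.050
# plankton  2.001  0.076
# symbiont  1.000  0.052

host = tps[tps.fraction == "host"].iloc[0]
est = heterotrophy_fraction((host.tp, host.tp_sd),
                            tp_auto=(1.0, 0.0), tp_het=(2.0, 0.0),
                            scenario="detritivory")
print(f"TP = {host.tp:.3f} ± {host.tp_sd:.3f}, "
      f"heterotrophy = {est.percent:.1f}% ± {est.percent_sd:.1f}%")
# TP = 1.004 ± 0.030, heterotrophy = 0.4% ± 3.0%

print(round(sum_v(table, host.sample_id).sum_v, 3))   # 0.229
```

Host and symbiont tissues sit at the producer trophic position (TP ≈ 1)
while the plankton end-member sits one full trophic step higher
(TP ≈ 2); the host's mixing fraction is indistinguishable from fully
autotrophic nutrition, and its ∑V is low (no sign of microbial amino-acid
resynthesis). Training a discriminant model on the mean-normalized
six-essential-amino-acid δ¹³C fingerprints of the nutrition sources
(symbiont vs plankton) classifies the sources perfectly under
leave-one-out cross-validation and assigns every host coral to the
autotrophic group:

```python
from aacsia import subset_matrix, mean_normalize, LinearDiscriminant
from aacsia.registry import EAA6_PANEL

mat = mean_normalize(subset_matrix(table, "C", EAA6_PANEL,
                                   fractions=["symbiont", "plankton"]))
lda = LinearDiscriminant(mat)
print(lda.loocv()["overall"])                      # 1.0
hosts = mean_normalize(subset_matrix(table, "C", EAA6_PANEL, fractions=["host"]))
pred = lda.fit().predict(hosts, coarse_groups={"symbiont": "autotrophy",
                                               "plankton": "heterotrophy"})
print(pred["coarse_group"].value_counts().to_dict())   # {'autotrophy': 6}
```

The same chain is available end-to-end from the shell:

```bash
aacsia simulate --seed 1 --out sim --n-plankton 6
aacsia tp --input sim/isotopes.csv --output tp.csv
aacsia permanova --input sim/isotopes.csv --output perm.csv --element N --seed 1
aacsia fingerprint --input sim/isotopes.csv --output assignments.csv
aacsia run --config cfg.yaml     # full pipeline from a YAML config
```

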