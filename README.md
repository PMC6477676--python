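# stau-rnaloc

Quantitative analysis of Staufen-dependent mRNA localization and
RNA binding, in two branches that are usually analysed together when
dissecting a multi-domain RNA-binding protein:

1. **Binding models for SPR-style data.** Steady-state isotherms —
   one-site `R = Rmax·C/(KD + C)`, two-site
   `R = Rmax1·C/(KD1 + C) + Rmax2·C/(KD2 + C)` (KD1 ≤ KD2), and Hill
   `R = Rmax·Cⁿ/(KDⁿ + Cⁿ)` — with multi-start nonlinear least-squares
   fitting, AICc model selection, and censoring of dissociation
   constants above the largest tested concentration (reported as
   `"> Cmax nM"`). Kinetic sensorgrams are modelled with the
   bivalent-analyte scheme (A + L ⇌ AL, AL + L ⇌ AL₂; rate constants
   ka1, kd1, ka2, kd2; response R = AL + AL₂) integrated as an ODE and
   fitted jointly across analyte concentrations.
2. **Quantitative smFISH in oocytes.** Per-oocyte spot signal is
   redistributed into a 100 × 100 anteroposterior distribution matrix
   (column = 1% of the AP axis), from which a centre-of-mass offset and
   a posterior fraction (≥ 2-fold enrichment rule) are extracted and
   compared across genotypes (Kruskal–Wallis + pairwise Mann–Whitney U
   vs a reference, Bonferroni-corrected). mRNP copy numbers are
   calibrated by Gaussian-mixture fitting of a single-molecule-dominated
   intensity distribution (unit = mean of the largest-weight component)
   and binned by the 2ⁱ rule (1, 2:3, 4:7, …, 256:511). Protein
   colocalization is scored by nearest-neighbour pairing against a
   randomization null (particle positions redrawn uniformly inside the
   oocyte), and protein-per-copy scaling slopes are fitted and compared
   through interaction contrasts.

A synthetic-data generator produces oocytes, spot tables, rendered
images, binding curves and sensorgrams with known ground truth, so
every estimator is validated by parameter recovery. Fit-shaped
operations are sklearn-style estimators (`fit`/`predict`/`transform`,
`get_params`) and compose with sklearn tooling.

## Worked example

```python
import numpy as np
from stau_rnaloc import NoiseSpec, make_oocyte, simulate_rna_spots
from stau_rnaloc.binding import fit_steady_state
from stau_rnaloc.synthetic import simulate_binding_curve
from stau_rnaloc.quantify import UnitIntensityCalibrator
from stau_rnaloc.distribution import oocyte_descriptors

# two-site binding: simulate a noiseless titration and refit it
conc = np.geomspace(1, 1000, 12)
curve = simulate_binding_curve(
    "two_site", dict(kd1=18, kd2=2000, rmax1=50, rmax2=50), conc)
fit = fit_steady_state(curve, "two_site", seed=0)
print(f"KD1 = {fit.params_['kd1']:.1f} nM, KD2 = {fit.params_['kd2']:.0f} nM "
      f"(censored: {fit.censored_repr_.get('kd2', 'no')})")

# smFISH branch: posterior-localized oocyte with multi-copy mRNPs
annot = make_oocyte(100, 50, seed=0)
spots, truth = simulate_rna_spots(
    annot, 3000, copy_geometric_p=0.8, unit_intensity=100.0,
    frac_posterior=0.8, pole_spread=2.0, noise=NoiseSpec(cv=0.2, seed=7))
cal = UnitIntensityCalibrator(random_state=0).fit(spots["intensity"])
print(f"unit intensity = {cal.unit_intensity_:.1f} a.u. "
      f"(portion {cal.portion_:.2f}, smallest-mean consistent: {cal.consistent_})")
desc = oocyte_descriptors(spots, annot)
print(f"centre of mass (AP) = {desc['com_ap']:+.3f}, "
      f"posterior fraction = {desc['posterior_fraction']:.3f}")
```

Output:

```
KD1 = 18.0 nM, KD2 = 2000 nM (censored: > 1000 nM)
unit intensity = 98.4 a.u. (portion 0.77, smallest-mean consistent: True)
centre of mass (AP) = +0.380, posterior fraction = 0.782
```

The refit recovers the generating high-affinity constant exactly and
flags the low-affinity site as unresolvable within the tested range
(KD2 > 1 µM). The calibrated unit intensity is within 2% of the
generating 100 a.u. with the dominant (77%) component also the
lowest-mean one, and the oocyte simulated with 80% posterior
localization yields a posterior fraction of 0.78 and a centre of mass
shifted toward the posterior pole.

## Command line

```bash
stau-rnaloc run --seed 1 --out run_output          # full demo pipeline
stau-rnaloc simulate oocyte --seed 0 --out sim/    # spot tables + annotation
stau-rnaloc fit-binding --model auto --in curve.csv --out fit.json
stau-rnaloc quantify --spots spots.csv --out quant/
stau-rnaloc colocalize --rna rna.csv --protein gfp.csv \
    --copies quant/copy_numbers.csv --annot annot.json --out coloc/
stau-rnaloc distribution --manifest manifest.csv --reference stau_null --out dist/
```

`run` executes simulate → quantify → distribution → colocalize →
fit-binding from one YAML config and a single global seed; re-running
with the same config and seed reproduces identical numerical outputs.

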