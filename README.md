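# polysize

Predicting the size of polymer nanoparticles directly from chemical
structure and formulation parameters.

When a hydrophobic polymer dissolved in a water-miscible solvent (THF) is
added to water, it precipitates into nanoparticles whose hydrodynamic
diameter depends on the polymer's repeat-unit chemistry, its degree of
polymerization *Dp*, the stock concentration, and the presence of a
surfactant.  `polysize` is for polymer chemists and formulation scientists
who want a structure-aware regression model of that process: it learns the
mapping (repeat unit, *Dp*, concentration, surfactant) → z-average diameter
from DLS screening data and generalizes to repeat units it has never seen.

## The model

The repeat unit — a SMILES string with two `*` markers on the backbone
attachment atoms, e.g. `*CC(*)(C)C(=O)OC` for methyl methacrylate — is built
into a **cyclic macrocycle of 10 units**.  Because every unit in the ring has
an identical environment, each atom sees exactly what an interior atom of an
infinitely long chain sees, at a fraction of the cost of building the real
chain; the equivalence holds as long as no node feature encodes membership in
the macrocycle and the network's receptive field does not wrap around the
ring.

Atoms are featurized (element, heavy-atom degree, formal charge,
hybridization, H count, iterative partial charge; 27 dimensions) and passed
through stacked graph convolutions

$$H_{n+1} = \sigma\!\left(\tilde D^{-1/2}\,\tilde A\,\tilde D^{-1/2}\, H_n W_n + b_n\right),$$

where $\tilde A = A + I$ adds self-loops and $\tilde D$ is its degree matrix.
A readout (column-wise max ‖ gated weighted sum) reduces the node features to
a fixed 128-length fingerprint, which is concatenated with the standardized
formulation numerics and regressed through fully connected layers
$l_{n+1} = \sigma(l_n W_{n+1} + b_{n+1})$ to a single size in nm.  Training
minimizes the mean absolute percentage error

$$\mathrm{MAPE} = \frac{100}{n}\sum_i \frac{|\hat y_i - y_i|}{y_i},$$

so small particles are predicted as carefully as large ones.  The networks
are implemented natively in NumPy (float64, explicit backpropagation, Adam),
which keeps evaluation bit-deterministic.

Around the model the package provides

* **DLS data cleaning** — invalid-sample removal (missing size, high PDI,
  out-of-bounds size) and robust within-formulation replicate-outlier
  rejection, with machine-readable reason codes;
* **leave-one-polymer-out (LOPO) evaluation** — retrain with every record of
  one polymer removed, test on it, and decompose the error to find the worst
  performing parameter group (by *Dp*, concentration, or additive);
* **a synthetic study generator** with a known, graph-learnable ground-truth
  size law, used by the entire test suite.

## Worked example

```python
import polysize as ps

data = ps.generate_clean_dataset(ps.SynthConfig(seed=7))   # 2700 records
cfg  = ps.ModelConfig(max_epochs=120, patience=40, seed=7)
res  = ps.ParticleSizeModel(data, cfg).fit()
print(res.summary())
```

```
Particle-size GCN regression results
====================================================
repeat units:        10
conv layers:         4 x 64 (fingerprint 128)
fc layers:           128 -> 64 -> 32 -> 1
cyclic ring size:    10
dropout:             0.1
epochs run:          78 (best: 36)
n train / val:       2160 / 540
train MAPE / RMSE:   4.39 % / 12.1 nm
val   MAPE / RMSE:   4.26 % / 11.1 nm
====================================================
```

The validation error of ~4 % MAPE (≈11 nm RMSE) means the model has
recovered the generator's size law to within its 5 % measurement noise.
Predictions for a new formulation:

```python
for conc in (1.0, 10.0, 30.0):
    s = res.predict("*CC(*)(C)C(=O)OCCCC", dp=150.0, conc_gL=conc)
    print(f"poly(butyl methacrylate), Dp=150, c={conc:>4} g/L -> {s:.1f} nm")
```

```
poly(butyl methacrylate), Dp=150, c= 1.0 g/L -> 80.1 nm
poly(butyl methacrylate), Dp=150, c=10.0 g/L -> 177.1 nm
poly(butyl methacrylate), Dp=150, c=30.0 g/L -> 269.5 nm
```

Sizes grow with concentration, as planted in the generator (and as observed
in nanoprecipitation practice).  The same model objects expose
`prediction_surface` (a *Dp* × concentration grid), `plot_training`,
`plot_surface`, JSON bundle `save`/`load`, and `leave_one_polymer_out`.

A command-line interface covers the whole pipeline:

```bash
polysize simulate --out raw.csv --seed 1
polysize preprocess --in raw.csv --out clean.csv --rejects rejects.csv
polysize train --data clean.csv --out model.json --seed 1
polysize lopo --data clean.csv --holdout "poly(methyl methacrylate)" --out lopo.json --seed 1
polysize predict --model model.json --smiles "*CC(*)(C)C(=O)OC" --dp 150 --conc 10
polysize fingerprint-convergence --out convergence.csv --seed 0
```

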