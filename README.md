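# protonpocket

Analysis toolkit for the cation-binding pocket of the gastric H⁺,K⁺-ATPase
(and related P₂-type ATPases) in its luminal-open E₂P state. The pump
exchanges protons for K⁺ across the parietal-cell membrane against a
million-fold H⁺ gradient; which of the five pocket carboxylates (E343, E795,
E820, D824, D942) carry protons controls how many K⁺ ions bind and how
protons redistribute after binding. This package implements the
post-processing a simulator needs around classical MD of that system:

* **Protonation-state enumeration** — all microstates of the five-residue
  pocket with a chosen proton count; the standard ensemble is the 20 states
  with two or three protons, three replicates each (60 trajectories,
  750 ns per state).
* **Dynamic pKa correlation analysis** — per-frame pKa series (ingested from
  an external empirical predictor, or from a built-in structure-based
  stand-in) are correlated pairwise over the trailing 100 ns of each
  trajectory using the Pearson coefficient

  r = Σₜ (xₜ − x̄)(yₜ − ȳ) / √Σₜ (xₜ − x̄)² √Σₜ (yₜ − ȳ)²,

  with 99% Fisher-z confidence intervals.
* **Proton-transfer network inference** — residue pairs with exactly one
  protonated member and strongly anti-correlated pKa (r < −0.5) in a
  trajectory are transfer hypotheses (donor = the protonated residue);
  instances are counted over the ensemble, filtered by spatial proximity,
  and assembled into a directed, weighted network.
* **K⁺-binding occupancy** — coordination-based bound-ion detection
  (≥ 2 pocket oxygens within 0.35 nm), site I/II vs site III classification
  (aspartate-majority coordination), end-of-trajectory occupancy means with
  standard errors, and the occupancy-vs-protonated-glutamate correlation
  that probes the transport-stoichiometry-variation hypothesis.
* **Umbrella sampling / WHAM** — window planning (47 windows, 0.20–2.50 nm,
  0.05 nm spacing, k = 5000 kJ/mol·nm², 310 K), the self-consistent 1-D
  weighted-histogram estimate G(z) = −k_BT ln P(z), block-bootstrap errors,
  bulk-zero alignment, and binding free energies.
* **Synthetic data generators** — Gaussian AR(1) pKa ensembles with planted
  cross-correlations, stochastic ion-binding trajectories with calibrated
  endpoint occupancies, and Boltzmann-exact umbrella window samples from a
  known potential, so the entire pipeline is testable without MD data.

## Worked example

Correlation analysis of one synthetic trajectory of the E795⁺D824⁺D942⁺
state (the protonation state the free-energy analysis singles out as the
optimal K⁺ acceptor), with the E795/E820 pair generated at ρ = −0.923:

```python
from protonpocket import parse_label, correlation_matrix, candidate_pairs, top_k_pairs
from protonpocket.synth import PkaEnsembleSpec, gen_pka_series

state = parse_label("E795+D824+D942+")
spec = PkaEnsembleSpec(seed=11, planted_pairs={("E795", "E820"): -0.923})
series = gen_pka_series(state, 0, spec)          # 250 frames, 1 ns spacing
mat = correlation_matrix(series, window_ns=100.0, ci_level=0.99)
for entry in top_k_pairs(mat, 3):
    a, b = entry["pair"]
    lo, hi = entry["ci"]
    print(f"{a}-{b}: r = {entry['r']:+.3f}   99% CI [{lo:+.3f}, {hi:+.3f}]")
for p in candidate_pairs(mat):
    print(f"transfer hypothesis: {p.donor}+ -> {p.acceptor}  (r = {p.r:+.3f})")
```

prints

```
E795-E820: r = -0.920   99% CI [-0.952, -0.869]
D824-D942: r = +0.392   99% CI [+0.151, +0.589]
E795-D942: r = +0.142   99% CI [-0.118, +0.384]
transfer hypothesis: E795+ -> E820  (r = -0.920)
```

The sample coefficient recovers the planted anti-correlation within its
interval, and because only E795 of the pair is protonated the pair survives
the transfer criteria with E795 as the donor. Two residues that are both
protonated (or both deprotonated) would be excluded no matter how negative
their r.

A free-energy round trip through the umbrella/WHAM machinery (samples drawn
from a known binding potential with a −12 kJ/mol well):

```python
from protonpocket.synth import gen_umbrella_samples
from protonpocket.pmf import wham, align_pmf, binding_free_energy

windows = gen_umbrella_samples(n_samples=20000, seed=1)   # 47 biased windows
profile = align_pmf(wham(windows, n_bins=200), bulk_region=(2.0, 2.45))
dg = binding_free_energy(profile, binding_region=(0.3, 0.8))
print(f"K+ binding free energy: {dg['dg_kj_per_mol']:.2f} kJ/mol ({dg['dg_kt']:.2f} kT)")
```

prints

```
K+ binding free energy: -11.77 kJ/mol (-4.57 kT)
```

i.e. the estimator recovers the planted well depth to a fraction of k_BT.

## Command line

A `protonpocket` console script wraps the library: `generate` (synthetic
ensemble inputs), `correlate` (matrix + top pairs for one pKa table),
`network` / `binding` / `report` (ensemble-scale runs writing a bundle of
CSV/JSON/DOT outputs plus a manifest), `pmf` (WHAM from window sample
files), and `validate` (configuration checks). Exit codes: 0 success,
2 usage, 3 data, 4 convergence.

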