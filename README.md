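# mocolab

Head-motion characterization and correction-strategy comparison for
block-design task fMRI, evaluated end-to-end on synthetic BOLD phantoms.

Head motion corrupts task-fMRI activation estimates in two ways: gradual
drift of the head and sudden movements ("motion outliers" or spikes). The
common remedies — regressing out 6 or 24 rigid-body motion parameters (MPs),
adding one-hot *scrubbing* regressors for outlier volumes detected by
framewise displacement (FD) or DVARS, or *interpolating* outlier volumes
from their neighbors — are easy to apply but hard to choose between,
especially for clinical populations that move more. `mocolab` implements
the full comparison as a tested pipeline: simulate a phantom with known
activation, motion and noise; quantify motion; apply each of the nine
correction models; map activation with a GLM; and score each model by its
activation quality metrics.

It is written for methods researchers and pipeline builders who want a
controlled testbed where the ground truth is known — not a replacement for
a clinical preprocessing stack.

## The models at the core

**Motion metrics.** Framewise displacement sums the absolute frame-to-frame
changes of the six rigid-body parameters, rotations converted to arc length
on a 50 mm sphere:

    FD_i = |Δd_ix| + |Δd_iy| + |Δd_iz| + 50·(|Δα_i| + |Δβ_i| + |Δγ_i|),

with outliers at FD > 0.5 mm. DVARS is the spatial RMS over the brain of
the temporal intensity difference, ⟨(I_i − I_{i−1})²⟩^{1/2}, in % ΔBOLD,
with outliers above the per-run boxplot threshold P75 + 1.5·IQR. The
motion-explained variance of the mean BOLD signal b on P motion regressors
is the dof-adjusted coefficient of determination
R²_adj = 1 − (N−1)/(N−P−1)·SS_res/SS_tot.

**Correction.** Nine models per run: realign-only; 6 or 24 MPs as nuisance
regressors (24 = Friston expansion [MP, MP², ΔMP, (ΔMP)²]); either MP set
plus FD- or DVARS-triggered scrubbing; either MP set plus linear temporal
interpolation of FD-flagged volumes.

**Activation.** Voxelwise GLM b = Xβ + ε with double-gamma-HRF-convolved
boxcar task regressors, DCT drift columns and an intercept; contrast t
scores probit-matched to Z; Bonferroni voxel threshold plus minimum cluster
extent. Each thresholded map is scored by Z-max (highest surviving Z) and
Z-mean (mean Z over surviving-cluster voxels).

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Simulate one localizer run (192 volumes, TR 1 s) with drift, two transient
1 mm spikes and their intensity artifacts, realign it, and run the
nine-model comparison:

```python
from mocolab.harness import simulate_run, run_model_suite, SuiteConfig, StudyConfig

run = simulate_run("localizer", seed=42, config=StudyConfig(seed=0))
res = run_model_suite(run, SuiteConfig(hp_cutoff=run.hp_cutoff))

m = res.motion
print(f"meanFD={m.mean_fd:.3f} mm  meanFD'={m.mean_fd_prime:.3f}  "
      f"meanFD''={m.mean_fd_doubleprime:.3f}  spikes={m.n_spikes}")
for q in res.metrics:
    print(f"{q.model_id:12s}  Zmax={q.z_max:5.2f}  Zmean={q.z_mean:5.2f}")
```

prints

```
meanFD=0.114 mm  meanFD'=0.095  meanFD''=1.021  spikes=4
realign_only  Zmax=10.97  Zmean= 6.97
mp6           Zmax=11.33  Zmean= 7.19
mp24          Zmax=11.15  Zmean= 7.11
mp6_fd        Zmax=11.93  Zmean= 7.37
mp6_dvars     Zmax=11.97  Zmean= 7.37
mp6_interp    Zmax=11.95  Zmean= 7.34
mp24_fd       Zmax=11.03  Zmean= 7.07
mp24_dvars    Zmax=11.04  Zmean= 7.08
mp24_interp   Zmax=11.30  Zmean= 7.11
```

Reading it: overall motion is mild (meanFD 0.114 mm) but the spike frames
are violent (meanFD″ ≈ 1 mm, an order of magnitude above the non-outlier
frames). Every 6-MP outlier correction clearly beats plain 6-MP regression
(Z-max 11.9–12.0 vs 11.3), the 6-MP family beats the 24-MP family, and for
the 24-MP family only interpolation helps — the derivative columns of the
24-MP set already absorb most of the spike-frame artifact, so extra scrub
columns only cost task signal.

The same machinery is exposed on the command line:

```bash
moco-lab simulate --paradigm localizer --seed 42 --out run/
moco-lab metrics --bold run/localizer.nii.gz --mp run/rp_localizer.txt --out metrics.tsv
moco-lab glm --bold run/localizer.nii.gz --events run/localizer_events.tsv \
             --contrast "moving:1,static:-1" --hp 24 --out zmap.nii.gz
moco-lab reproduce --seed 0 --out results/
```

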