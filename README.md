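# tacdelay

Single-voxel tracer-arrival **delay estimation for dynamic PET**.

Before kinetic modeling of a dynamic PET scan, the transport delay between
the blood input function (measured in the aorta or by arterial sampling) and
each tissue region must be corrected, or the fitted rate constants are
biased.  On long-axial field-of-view scanners with ~1 s frames this can be
done per voxel — but single-voxel time-activity curves (TACs) are extremely
noisy.  `tacdelay` implements a delay-estimation algorithm built for exactly
that regime, two standard comparators, a synthetic validation harness, and
voxelwise delay-map generation for 4D NIfTI volumes.

## The algorithm

The tracer-arrival onset of a curve is found by fitting its *cumulatively
summed* TAC, which suppresses zero-mean reconstruction noise.  With frame
mid-times t and frame-spacing weights, the summed curve is fitted by the
antiderivative of a logistic rise:

    A(t)    = a / (1 + exp((c − t)/b))
    Asum(t) = a·b·ln(exp((c − t)/b) + 1) + a·(t − c)
    T       = c − 3.5·b

where `a` is the asymptotic slope, `c` the transition centre (s) and `b` the
transition tightness (s); the empirical shape factor 3.5 pulls the onset
from the centre back to the foot of the rise.  Robustness machinery: early
spurious-bolus plateaus in the summed curve are detected and subtracted; up
to 10 candidate fit ranges (endpoints at the largest second-derivative
peaks) are fitted with bounded least squares; fits are filtered
(R² ≥ 0.8, onset positive and inside the range) and the median over the top
half by R² gives the onset.  The delay is

    ΔT = T_tissue − T_input

with both curves run through the identical pipeline.  Comparators: lag of
maximum cross-correlation, and a one-tissue compartment model
dC_T/dt = K1·C_A(t − delay) − k2·C_T with jointly fitted delay.

## Worked example

Estimate the delay between a simulated tissue curve (true delay 5 s,
K1 = 50 ml/100g/min, k2 = 1 /min, single-voxel noise σ = 0.4) and the bolus
input function:

```python
from tacdelay import SCHEDULES, INPUT_PRESETS, SimulationSpec, simulate_tissue
from tacdelay import estimate_delay, estimate_onset
from tacdelay.synthetic import input_function_tac

sched = SCHEDULES("h2o")                       # 40x1s + 5x4s + 6x10s + 3x20s
model = INPUT_PRESETS["h2o_idif"]              # bolus arriving at 12 s
idif = input_function_tac(model, sched)

spec = SimulationSpec(K1=50, k2=1.0, delay=5.0, sigma=0.4, seed=7,
                      schedule=sched, input_model=model)
tissue = simulate_tissue(spec)

print(estimate_onset(idif).onset_time)         # 12.10  (true arrival 12 s)
print(estimate_delay(tissue, idif))            # 8.43   (true delay 5 s)
```

The input onset lands within 0.1 s of the true bolus arrival; the noisy
single-voxel delay estimate carries both this σ = 0.4 noise scatter and the
algorithm's systematic offset (the tissue curve rises more slowly than the
input, and the −3.5·b correction only partly compensates), which is the
residual-delay behaviour the benchmark below quantifies.

The same estimate from the command line, given TAC tables:

```sh
tacdelay estimate --tissue tissue.csv --input idif.csv --method proposed
```

prints the delay and onset diagnostics as JSON.  Voxelwise
maps: `tacdelay delay-map --pet dyn.nii.gz --timing dyn.json --input-curve
idif.csv --out delay.nii.gz` (failed voxels are retried on their 5×5×5
neighbourhood mean and NaN if still unfittable).

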