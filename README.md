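# larvatrack

Offline analysis for an optogenetic assay of *Drosophila* larval motor-neuron
performance. In the assay, motor neurons expressing channelrhodopsin-2 are
driven by a programmed blue-light cycle while an unrestrained 3rd-instar
larva crawls on an agar plate; a camera (blind to the blue light behind a
long-pass filter) records the animal at 10 frames/s together with a small
red indicator LED wired to the stimulus circuit. Body-wall contraction
shortens the larva's outline, so the **perimeter** of the segmented animal,
cycle by cycle, is the readout of motor-neuron output — and its decline over
a 20-minute trial is the readout of fatigue.

`larvatrack` is for experimenters running that (or any similar
stimulus-locked contraction) assay who want a scripted, reproducible version
of the usual interactive ImageJ/WrmTrck workflow, plus the synthetic
phantoms needed to validate every stage without recorded data.

## What it computes

Given frames `I_t`, the segmentation chain is Gaussian blur (radius 1) →
rolling-ball background subtraction (radius 50 px, on the photometric
inverse for a dark larva) → Otsu threshold → binary mask. The tracked
object's perimeter `P_t` is normalized by the pre-stimulus baseline,

    p_t = P_t / mean{ P_s : t_on − 2 s ≤ s < t_on },

where `t_on` is the first decoded light onset. For stimulation cycle *k*
with on-window `ON_k` and preceding off-window `OFF_{k−1}`:

    rest_k      = mean{ p_t : t in trailing half of OFF_{k−1} }   (rest_1 = 1)
    contract_k  = min { p_t : t in ON_k }
    amplitude_k = rest_k − contract_k

Fatigue is `mean(amplitude_{1..3})` vs `mean(amplitude_{last 3})`, and groups
of larvae are compared with a two-sided equal-variance Student's t-test on
per-larva amplitudes.

Protocol arithmetic: a 2 s-on / 1 s-off cycle is a 67 % duty cycle; relative
to the ~78 % duty cycle of endogenous fictive locomotion that is a
time-averaged metabolic load of 67/78 ≈ 86 %.

The package also quantifies presynaptic mitochondrial content from
two-channel fluorescence stacks: average-project each z-stack, subtract
adjacent-background ROI means from bouton ROI means in each channel, and
report mitochondrial/cytosolic signal as a ratio.

## Worked example

```python
from larvatrack import PhantomSpec, StimulusProtocol, duty_cycle, metabolic_load
from larvatrack.pipeline import PipelineConfig, run_pipeline
from larvatrack.phantom import ellipse_perimeter

dc = duty_cycle(2, 1)                      # 66.67 % -> reported 67 %
ml = metabolic_load(dc.rounded, 78)        # 85.90 % -> reported 86 %

spec = PhantomSpec(protocol=StimulusProtocol(total_s=70.0),
                   contraction_fraction=0.2, response_tau=0.15)
res = run_pipeline(PipelineConfig(phantom=spec, seed=1), write_outputs=False)
print(len(res.cycles), res.cycles["amplitude"].mean())
```

prints `20 0.1738...`: the 70 s phantom holds 20 complete 3 s cycles, and the
recovered mean contraction amplitude is 0.1738 against the analytic value of
0.1708 for a 20 % major-axis contraction of a 30 × 9 px ellipse
(`1 − P(24, 9)/P(30, 9)` with `P` the Ramanujan ellipse perimeter) — a 1.8 %
error carried entirely by pixelization. The same run reports
`first-3 amplitude 0.1751, last-3 0.1736, ratio 0.991`: no programmed
fatigue, none detected.

The same flow from a shell:

```sh
larvatrack simulate --out sim --total-s 70 --contraction-fraction 0.2 --seed 1
larvatrack analyze  --config my_config.yaml
larvatrack mito     --cyto cyto.tif --mito mito.tif --rois rois.json
larvatrack report   --group-a control_amps.csv --group-b kd_amps.csv
```

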