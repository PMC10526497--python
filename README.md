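# depthsim

Binocular depth estimation by inverting a hierarchical projective generative
model, with active vergence control.

A simulated agent carries a belief over a 2D target position (depth on the
`x` axis) and, through two parallel pathways, predicts what each of its two
"eyes" should see: the belief is mapped into each eye's reference frame by a
homogeneous roto-translation parameterised by a shared vergence-accommodation
angle pair, then projected onto the eye's camera plane by a pinhole model.
Prediction errors at the camera planes flow back through the analytic
adjoints of these transforms and update every belief by gradient descent on a
precision-weighted squared-error functional (predictive-coding message
passing). The same error pathways can move the eyes: an attractor on the
projected beliefs pulls them toward the camera-plane centres, and the
resulting proprioceptive errors drive eye rotation, so the agent fixates the
target while it infers its depth. Because the shared error pathways fight
when estimation and fixation run at once, the two are interleaved in
alternating perception/action phases.

The generative process supports a nonuniform-fovea condition in which the
visual noise standard deviation grows exponentially with the distance between
the fixation point and the target — under that condition fixating the target
is what makes depth estimation work, which is the point of the exercise.

## Layout

| module | contents |
| --- | --- |
| `depthsim.transforms` | homogeneous-coordinate geometry: roto-translations, eye extrinsics, pinhole projection, analytic adjoints, closed-form triangulation oracle |
| `depthsim.inference` | generic machinery: generalized beliefs (value + velocity), dynamic prediction-error units, action update, free-energy proxy |
| `depthsim.agent` | the four-level hierarchy, fixation attractor, phase scheduler |
| `depthsim.environment` | the generative process: true world, fovea noise, observations, eye kinematics |
| `depthsim.experiments` | trial runner, the three model variants, metrics, comparison reports |
| `depthsim._fast` | scalar fast path for the trial inner loop (pinned to the reference implementation by tests) |

## CLI

Run one condition (variant x resolution) and write per-trial/summary CSVs:

```sh
depthsim run --variant active --resolution nonuniform --trials 50 \
    --cycle-steps 100 --cycles 150 --k 1.5 --threshold 0.1 --seed 0 \
    --out results/ --trace
```

Variants: `parallel` (eyes fixed straight ahead, perception only),
`vergence` (eyes start fixated on the target), `active` (random initial
gaze, simultaneous estimation and fixation via action–perception cycles),
and `simultaneous` (no cycling — demonstrates the failure mode).

Run the full 3x2 grid and emit the comparison table, bar-chart figure and
machine-readable ordering verdicts:

```sh
depthsim compare --trials 50 --seed 0 --out results/
```

Agent parameters (precisions, gains, attractor gain, integration step) can
be overridden with `--config agent.yaml`, e.g. `lam: 5.0`.

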