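# dbareit

2D D-bar electrical impedance tomography (EIT) on circular domains, built
around a sinc-convolution solver for the D-bar integral equation, with a
complete synthetic-measurement stack and GREIT-style evaluation.

The full chain:

1. **forward_sim** — disk meshes, trigonometric current patterns, a
   complete-electrode-model (CEM) P1-FEM forward solver, chest / rotating-target
   / smooth phantoms, uniform measurement noise.
2. **dn_map** — discrete Neumann-to-Dirichlet and Dirichlet-to-Neumann maps
   from current/voltage frames, the best homogeneous conductivity fit
   (least squares through the origin), and the difference DN matrix.
3. **scattering** — truncated approximate scattering transform `t_R(k)`
   evaluated as a trigonometric-mode double series, zero outside `|k| <= R`.
4. **sinc_dbar** — the D-bar integral equation discretized at sinc points of
   `[-2R, 2R]^2` and solved via the four-quadrant separation-of-variables
   sinc convolution with real-linear GMRES; conductivity is read off as
   `gamma(x) = gamma_best * mu(x, 0)^2`.
5. **metrics** — amplitude response, position error, ringing, resolution,
   shape deformation, sup-norm convergence tables, degree of truth and
   relative extremum errors.
6. **cli_io** — YAML configuration, delimited-text interchange formats
   (datasets, DN matrices, scattering transforms, images), an EIDORS-style
   MAT-file reader, and the `dbareit` command line.

## Command line

```bash
# simulate a 16-electrode rotating-target protocol (nine datasets + refs)
dbareit simulate --scenario rotating --config cfg.yaml --out data/rot

# simulate + reconstruct a chest phantom
dbareit simulate --scenario chest-simulated --out data/chest
dbareit reconstruct --data data/chest --out out/chest

# nine-position accuracy study (AR, PE, RNG, RES, SD per position)
dbareit evaluate --config cfg.yaml --noise 0.1 --out out/metrics

# k-grid convergence sweep
dbareit sweep --config cfg.yaml --grid-sizes 16,32,64 --out out/sweep
```

A config file is a flat YAML mapping of `RunConfig` fields, e.g.

```yaml
L: 16            # electrodes
M: 1.0           # current amplitude (mA)
R: 3.0           # scattering truncation radius
m_idx: 8         # one-sided sinc index count (k-grid level 16)
image_size: 64
noise_amplitude: 0.1
seed: 7
```

Every dataset directory carries the measurement frame plus a homogeneous
reference frame (as collected in real tank experiments); the reconstruction
side consumes only these text frames — it never sees the forward mesh.

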