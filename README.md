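# skingetsim

Numerical comparison of pulse-delivery protocols for **gene electrotransfer
(GET) to skin** — electroporation-mediated delivery of plasmid DNA into
skin cells — for researchers designing electrode applicators and
commutation protocols.

Successful GET requires fields above the **reversible electroporation
(RE)** threshold (cells permeabilise and survive — the useful regime) while
avoiding the **irreversible (IRE)** threshold (cells die — collateral
damage).  `skingetsim` predicts both volumes for a given applicator and
protocol so that protocols can be ranked on the two competing criteria:
maximise RE volume, minimise IRE volume.

## The model

- **Skin**: eight plane-parallel layers (stratum corneum → muscle,
  27.35 mm) with anisotropic conductivity tensors, per-layer RE/IRE
  thresholds, and field-dependent conductivity
  σ(E) = σ0 · [1 + (f_max − 1) · g((E − E_re)/(E_ire − E_re))], a clamped
  sigmoid rising from 1 at the RE threshold to the layer's maximal increase
  (100× for the stratum corneum) at the IRE threshold.  Muscle's RE
  threshold depends on the field's angle to the fibers (80 V/cm ∥,
  200 V/cm ⊥).
- **Protocols**: ordered anode/cathode activation steps on a hexagonal
  applicator, each step followed by its polarity reversal —
  *classical* (7 electrodes, all 12 adjacent pairs, 24 steps),
  *alternative* (6 electrodes, rim pairs then opposite electrode pairs,
  18 steps, no central electrode), and the low-voltage *MEA* protocol
  (12 steps).  Pulse trains are validated against the generator envelope
  (80–600 V, 10–1000 µs, 0.1–5000 Hz).
- **Solver**: ∇·(σ(E)∇φ) = 0 per step on a structured finite-volume grid
  (Dirichlet contact discs, insulating boundaries), damped Picard iteration
  for the σ(E) self-consistency, and *sequential electroporation memory*:
  a per-voxel field envelope e_env = maxₖ |E⁽ᵏ⁾| that persistently raises
  the conductivity across steps.
- **Metrics**: per-layer RE/IRE volumes from envelope thresholding, RE
  penetration depth, field slices, and protocol-comparison percentages.
- **Imaging**: fluorescence transfection quantification — area above a
  threshold, mean intensity, integrated density (their product).

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```bash
python examples/04_protocol_comparison.py
```

runs both hex protocols at 560 V on the coarse preset and prints:

```
classical: RE   242.1 mm^3   IRE  7.85 mm^3   max RE depth 2.77 mm
alternative: RE   248.6 mm^3   IRE  6.43 mm^3   max RE depth 2.77 mm

alternative vs classical:
  RE volume gain:    +2.7 %   (larger reversibly electroporated volume = more tissue available for gene transfer)
  IRE reduction:     +18.1 %   (less irreversible damage = lower collateral cost)
```

The alternative protocol electroporates more tissue reversibly while
damaging less of it irreversibly: dropping the central electrode removes
the most intense field concentration, and the added cross-array pulses
(between opposite electrode pairs) push the field wider and deeper at the
same amplitude.  At the default resolution (where the reported numbers are
evaluated) the gains are ≈ +10 % RE and ≈ −16 % IRE, with the irreversible
damage concentrated in the stratum corneum directly under the electrodes.

Other examples: the layer stack and conductivity law (`01`), protocol
generation and device-envelope validation (`02`), a single-step field
solution (`03`), fluorescence quantification (`05`).

A thin CLI wraps the same calls:

```bash
skin-get-sim protocol --array hex6 --name alternative --out protocol.json
skin-get-sim simulate --resolution coarse --out-dir out/
skin-get-sim quantify img1.tif img2.tif --threshold 40 --out table.csv
```

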