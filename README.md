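# dnanchor

Trajectory analysis for DNA duplexes anchored in lipid bilayer membranes.

Chemically modified DNA — duplexes carrying a "belt" of alkylated
phosphorothioate (alkyl-PPT) base pairs, or cholesterol / porphyrin
anchors — can embed into lipid membranes, which makes such constructs
useful as membrane-addressable nanostructure components. Given molecular
dynamics (MD) trajectories of such systems (PDB topology + DCD/XTC
coordinates) this package quantifies, per construct:

* **Anchoring stability** — the Z coordinate of the modified segment's
  center of mass relative to the bilayer midplane, Z(t); its 20 ns block
  average; and a Gaussian fit A·exp(−(z−μ)²/2σ²) to the 0.2 Å-binned
  histogram of Z after a 200 ns equilibration discard. A small fitted σ
  means stiff anchoring. Membrane escape is flagged when |Z| exceeds a
  threshold for a sustained dwell.
* **DNA distortion** — the average base-pair rise per frame (distance
  between consecutive base-pair centers, C1′–C1′ midpoints; canonical
  B-form value 3.32 Å) and the number of broken base pairs (Watson–Crick
  N1–N3 proxy distance > 4.5 Å by default).
* **Membrane perturbation** — local bilayer thickness near the DNA,
  measured as the distance between the two leaflets' C2-atom density
  peaks using lipids within 15 Å (lateral) of the DNA, with a bulk
  profile for comparison; and the number of water molecules within 10 Å
  of the instantaneous midplane (mean ± SD over 2 ns blocks).
* **Pull-out energetics** — from steered-MD (SMD) records of a
  constant-velocity pull (0.5 Å/ns), the force averaged in 2 Å bins
  along the pulled group's CoM z, the cumulative work W(z) = ∫F dz
  (pN·Å and kcal/mol), and a ranking of constructs by total work.

Because all-atom trajectories of these systems are large and rarely
deposited, the package ships a first-class synthetic-data generator
(`dnanchor.synthetic`): an idealized B-form proxy duplex with exact step
geometry, noisy planar C2 leaflets with optional local thinning, exact
water-slab partitions, an Ornstein–Uhlenbeck (OU) model for the anchored
segment's CoM-Z with a controllable stationary SD, and SMD records with
closed-form work. Every analysis stage is validated against this ground
truth; real all-atom data flows through the same code paths via atom
selections.

## Worked example

Run the full pipeline on a synthetic centrally-anchored construct
(30 bp, 6-pair belt, 500 ns at 0.2 ns/frame, OU stationary SD 0.98 Å):

```python
from dnanchor.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    seed=7, outdir="demo_out", label="central-hexyl",
    generate={
        "bilayer": {"n_per_leaflet": 64, "box_xy": 60.0},
        "ou": {"stationary_sd": 0.98, "relaxation_time": 1.0,
                "dt": 0.2, "n_frames": 2500},
        "water": {"n_inside": 25, "n_outside": 200},
        "smd": {"profile": "gaussian", "amplitude": 60.0,
                 "center": 10.0, "width": 6.0, "z_start": 0.0, "z_end": 40.0},
    },
)
report = run_pipeline(cfg)
```

which prints (`report.metrics`):

```json
{
  "anchoring": {
    "fitted_sigma_A": 1.1041425581232187,
    "fitted_mu_A": -0.031881398216886715,
    "sample_sd_A": 1.0330561803249194,
    "sample_mean_A": -0.021203350666976085,
    "fit_residual": 6.28174208652346,
    "n_frames_analyzed": 1500,
    "escape_time_ns": null
  },
  "dna": {
    "mean_rise_A": 3.32,
    "broken_bp_mean": 0.0,
    "broken_bp_fraction": 0.0
  },
  "membrane": {
    "thickness_near_dna_A": 38.5,
    "thickness_bulk_A": 38.0,
    "water_count_mean": 25.0,
    "water_count_sd_block": 0.0
  },
  "smd": {
    "max_force_pN": 58.91525801703411,
    "total_work_pN_A": 859.2605321887612,
    "total_work_kcal_mol": 12.367197745919793
  }
}
```

Reading the numbers: the fitted σ of 1.10 Å recovers the generator's
0.98 Å stationary SD within the Monte-Carlo error of 1 500 analyzed
frames (the sample SD, 1.03 Å, agrees — the two are reported side by
side as a fit diagnostic); the duplex stays ideal (rise exactly 3.32 Å,
no broken pairs) because the generator moves it rigidly; the flat,
unthinned bilayer gives near-DNA and bulk thickness both ≈ 38 Å (peak
positions quantized by the 0.5 Å histogram bin); all 25 slab waters are
counted with zero block variance; and pulling against a Gaussian force
barrier of amplitude 60 pN costs 859 pN·Å ≈ 12.4 kcal/mol of work.

The same analyses run file-based from the shell:

```bash
dnanchor generate  --config demo.yaml --out gen/
dnanchor anchoring --traj gen/system.dcd --top gen/system.pdb \
    --belt-sel "resid 13:18 and ( chain A or chain B )" \
    --block-ns 20 --bin 0.2 --discard-ns 200
dnanchor smd --record pull.tsv --bin 2
dnanchor report run_a/report.json run_b/report.json
```

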