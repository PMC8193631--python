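"""End-to-end orchestration: config, generation, analyses, report.

A single YAML config drives one run: either synthetic inputs are
generated (construct + bilayer + anchored trajectory + pull record) or
existing files are loaded, the requested analyses execute, and every
metric lands in per-metric TSV files plus one ``report.json`` with a
provenance block (config hash, seed, package version) sufficient to
reproduce the numbers exactly.

All analysis defaults are the standard protocol values: 20 ns block
average, 0.2 Å histogram bins, 200 ns equilibration discard, 15 Å
near-DNA cutoff, 10 Å water half-width, 2 Å force bins, 2 ns SD blocks,
0.5 Å/ns pull velocity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dnanchor import anchoring, dna_structure, membrane, smd
from dnanchor.io_model import (
    ConstructSpec,
    Selection,
    TrajectorySet,
    belt_resid_range,
    read_structure,
    read_trajectory,
    select,
)
from dnanchor import synthetic
from dnanchor.synthetic import (
    BDnaParams,
    BilayerParams,
    ConstantForce,
    GaussianForce,
    LinearForce,
    OUParams,
    ThinningSpec,
)

__all__ = ["RunConfig", "Report", "run_pipeline", "combine_reports"]

log = logging.getLogger("dnanchor")

ANALYSES = ("anchoring", "dna", "membrane", "smd")

#: Tunables that must match before two runs may be compared side by side.
_COMPARABLE_KEYS = (
    "block_ns",
    "bin_A",
    "discard_ns",
    "broken_cutoff_A",
    "thickness_cutoff_A",
    "thickness_bin_A",
    "water_half_width_A",
    "sd_block_ns",
    "force_bin_A",
)


@dataclass
class AnalysisParams:
    block_ns: float = 20.0
    bin_A: float = 0.2
    discard_ns: float = 200.0
    broken_cutoff_A: float = 4.5
    thickness_cutoff_A: float = 15.0
    thickness_bin_A: float = 0.5
    water_half_width_A: float = 10.0
    sd_block_ns: float = 2.0
    force_bin_A: float = 2.0
    escape_threshold_A: float | None = None  # default: leaflet |z| + 10
    escape_dwell_ns: float = 10.0
    rise_window: str = "all"


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    seed: int = 0
    outdir: str = "dnanchor_out"
    label: str = "construct"
    analyses: tuple[str, ...] = ANALYSES
    construct: dict = field(default_factory=lambda: {
        "n_bp": 30, "belt_position": "central", "ppt_pairs": 6,
        "alkyl": "hexyl", "anchor": "alkyl-PPT",
    })
    generate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    selections: dict = field(default_factory=dict)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}; valid: {ANALYSES}")
        if isinstance(self.analysis, dict):
            self.analysis = AnalysisParams(**self.analysis)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analyses"] = list(self.analyses)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Report:
    label: str
    metrics: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"label": self.label, "metrics": self.metrics, "provenance": self.provenance}


def _build_force_profile(cfg: dict):
    kind = cfg.get("profile", "gaussian")
    if kind == "constant":
        return ConstantForce(cfg.get("f0", 10.0))
    if kind == "linear":
        return LinearForce(cfg.get("slope", 1.0), cfg.get("intercept", 0.0))
    if kind == "gaussian":
        return GaussianForce(
            cfg.get("amplitude", 60.0), cfg.get("center", 10.0), cfg.get("width", 6.0)
        )
    raise ValueError(f"unknown SMD force profile {kind!r}")


def _generate_system(config: RunConfig):
    """Build the synthetic system described by the config."""
    gen = config.generate
    spec = ConstructSpec(**config.construct)
    bdna = BDnaParams(n_bp=spec.n_bp, **gen.get("bdna", {}))
    dup_top, dup_coords = synthetic.gen_bdna(bdna)

    bil_kwargs = dict(gen.get("bilayer", {}))
    if "thinning" in bil_kwargs and bil_kwargs["thinning"] is not None:
        bil_kwargs["thinning"] = ThinningSpec(**bil_kwargs["thinning"])
    bilayer = BilayerParams(**bil_kwargs)

    ou_kwargs = dict(gen.get("ou", {}))
    ou_kwargs.setdefault("seed", config.seed)
    ou = OUParams(**ou_kwargs)

    water_cfg = gen.get("water")
    water = None
    if water_cfg:
        lz = 2.0 * (bilayer.leaflet_z + 40.0)
        water = synthetic.gen_water_slab(
            n_inside=water_cfg.get("n_inside", 30),
            n_outside=water_cfg.get("n_outside", 300),
            half_width=water_cfg.get("half_width", 10.0),
            box=(bilayer.box_xy, bilayer.box_xy, lz),
            seed=config.seed + 1,
        )

    belt_range = belt_resid_range(spec)
    if belt_range is not None:
        belt_query = f"resid {belt_range.start}:{belt_range.stop - 1} and ( chain A or chain B )"
    else:
        belt_query = "chain A or chain B"
    belt = select(dup_top, belt_query)
    traj = synthetic.gen_anchored_trajectory(
        (dup_top, dup_coords), bilayer, ou, belt=belt, water=water
    )
    selections = {
        "belt": belt_query,
        "dna": "chain A or chain B",
        "c2": "name C2 and resname POPC",
        "water": "name O and resname HOH",
    }
    selections.update(config.selections)
    return spec, traj, selections, bilayer


def _load_system(config: RunConfig):
    spec = ConstructSpec(**config.construct)
    top, _ = read_structure(config.inputs["topology"])
    traj = read_trajectory(top, config.inputs["trajectory"])
    selections = dict(config.selections)
    for key in ("belt", "dna", "c2"):
        if key not in selections:
            raise ValueError(f"loading external data requires a {key!r} selection")
    return spec, traj, selections, None


def run_pipeline(config: RunConfig) -> Report:
    """Execute the configured analyses and write all outputs.

    Deterministic given the config (seeds included); any stage error
    aborts with the stage named, leaving earlier outputs in place.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics: dict = {}
    stage = "setup"
    t_start = _time.perf_counter()
    try:
        needs_traj = any(a in config.analyses for a in ("anchoring", "dna", "membrane"))
        traj = None
        if needs_traj:
            if config.inputs.get("trajectory"):
                spec, traj, selections, bilayer = _load_system(config)
            else:
                spec, traj, selections, bilayer = _generate_system(config)
            log.info("system ready: %d atoms, %d frames", traj.n_atoms, traj.n_frames)
        else:
            spec = ConstructSpec(**config.construct)
            selections, bilayer = dict(config.selections), None
        p = config.analysis

        if "anchoring" in config.analyses:
            stage = "anchoring"
            t0 = _time.perf_counter()
            belt_sel = select(traj.topology, selections["belt"])
            c2_sel = select(traj.topology, selections["c2"])
            trace = anchoring.com_z_trace(traj, belt_sel, c2_sel)
            blocks = anchoring.block_average(trace, p.block_ns)
            fit = anchoring.fit_gaussian(trace, p.bin_A, p.discard_ns)
            thr = p.escape_threshold_A
            if thr is None:
                leaflet = bilayer.leaflet_z if bilayer is not None else 19.0
                thr = leaflet + 10.0
            esc = anchoring.escape_time(trace, thr, p.escape_dwell_ns)
            pd.DataFrame({"time_ns": trace.times, "z_A": trace.z}).to_csv(
                outdir / "com_z_trace.tsv", sep="\t", index=False
            )
            pd.DataFrame({"time_ns": blocks.times, "z_A": blocks.z}).to_csv(
                outdir / "com_z_blocks.tsv", sep="\t", index=False
            )
            centers = 0.5 * (fit.bin_edges[:-1] + fit.bin_edges[1:])
            pd.DataFrame({"z_A": centers, "count": fit.counts}).to_csv(
                outdir / "com_z_histogram.tsv", sep="\t", index=False
            )
            metrics["anchoring"] = {
                "fitted_sigma_A": fit.sigma,
                "fitted_mu_A": fit.mu,
                "sample_sd_A": fit.sample_sd,
                "sample_mean_A": fit.sample_mean,
                "fit_residual": fit.fit_residual,
                "n_frames_analyzed": fit.n_frames,
                "escape_time_ns": esc,
            }
            log.info("anchoring done in %.1f s", _time.perf_counter() - t0)

        if "dna" in config.analyses:
            stage = "dna"
            t0 = _time.perf_counter()
            pairing = dna_structure.BasePairing.from_duplex(spec.n_bp)
            rise = dna_structure.average_rise(traj, pairing, window=p.rise_window)
            times_b, broken = dna_structure.broken_bp_count(
                traj, pairing, cutoff=p.broken_cutoff_A, window=p.rise_window
            )
            pd.DataFrame(
                {"time_ns": rise.times, "mean_rise_A": rise.mean_rise, "broken_bp": broken}
            ).to_csv(outdir / "dna_structure.tsv", sep="\t", index=False)
            metrics["dna"] = {
                "mean_rise_A": float(rise.mean_rise.mean()),
                "broken_bp_mean": float(broken.mean()),
                "broken_bp_fraction": float(broken.mean()) / len(pairing),
            }
            log.info("dna done in %.1f s", _time.perf_counter() - t0)

        if "membrane" in config.analyses:
            stage = "membrane"
            t0 = _time.perf_counter()
            c2_sel = select(traj.topology, selections["c2"])
            dna_sel = select(traj.topology, selections["dna"])
            thick = membrane.local_thickness(
                traj,
                c2_sel,
                dna_sel,
                cutoff=p.thickness_cutoff_A,
                bin_width=p.thickness_bin_A,
                discard_ns=p.discard_ns,
            )
            rows = []
            for prof in (thick.near_dna, thick.bulk):
                if prof is None:
                    continue
                for zg, du, dl in zip(prof.z_grid, prof.density_upper, prof.density_lower):
                    rows.append((prof.region, zg, du, dl))
            pd.DataFrame(
                rows, columns=["region", "z_A", "density_upper", "density_lower"]
            ).to_csv(outdir / "membrane_profile.tsv", sep="\t", index=False)
            metrics["membrane"] = {
                "thickness_near_dna_A": thick.near_dna.thickness,
                "thickness_bulk_A": thick.bulk.thickness if thick.bulk else None,
            }
            if "water" in selections:
                try:
                    water_sel = select(traj.topology, selections["water"])
                except Exception:
                    water_sel = None
                if water_sel is not None:
                    wc = membrane.water_midplane_count(
                        traj,
                        water_sel,
                        c2_sel,
                        half_width=p.water_half_width_A,
                        discard_ns=p.discard_ns,
                        sd_block_ns=p.sd_block_ns,
                    )
                    pd.DataFrame({"time_ns": wc.times, "count": wc.counts}).to_csv(
                        outdir / "water_counts.tsv", sep="\t", index=False
                    )
                    metrics["membrane"]["water_count_mean"] = wc.mean
                    metrics["membrane"]["water_count_sd_block"] = wc.sd_block
            log.info("membrane done in %.1f s", _time.perf_counter() - t0)

        if "smd" in config.analyses:
            stage = "smd"
            t0 = _time.perf_counter()
            if config.inputs.get("smd_record"):
                rec = smd.read_smd(config.inputs["smd_record"], label=config.label)
            else:
                smd_cfg = config.generate.get("smd", {})
                rec = synthetic.gen_smd_record(
                    _build_force_profile(smd_cfg),
                    z_start=smd_cfg.get("z_start", 0.0),
                    z_end=smd_cfg.get("z_end", 40.0),
                    velocity=smd_cfg.get("velocity", 0.5),
                )
                rec.label = config.label
                smd.write_smd(rec, outdir / "smd_record.tsv")
            profile = smd.bin_force(rec, bin_width=p.force_bin_A)
            curve = smd.work_curve(rec)
            pd.DataFrame(
                {
                    "z_A": profile.z_bin_centers,
                    "mean_force_pN": profile.mean_force,
                    "count": profile.counts,
                }
            ).to_csv(outdir / "force_profile.tsv", sep="\t", index=False)
            pd.DataFrame(
                {
                    "z_A": curve.z,
                    "work_pN_A": curve.work_pN_A,
                    "work_kcal_mol": curve.work_kcal_mol,
                }
            ).to_csv(outdir / "work_curve.tsv", sep="\t", index=False)
            metrics["smd"] = {
                "max_force_pN": float(profile.mean_force.max()),
                "total_work_pN_A": curve.total_pN_A,
                "total_work_kcal_mol": curve.total_kcal_mol,
            }
            log.info("smd done in %.1f s", _time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    import dnanchor

    report = Report(
        label=config.label,
        metrics=metrics,
        provenance={
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "dnanchor_version": dnanchor.__version__,
            "numpy_version": np.__version__,
        },
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    log.info("pipeline finished in %.1f s", _time.perf_counter() - t_start)
    return report


def combine_reports(paths: list[str | Path]) -> pd.DataFrame:
    """Combine per-construct reports into one comparison table.

    Refuses to compare runs analyzed with different tunables (block
    size, bins, cutoffs, discard) — cross-construct comparisons are
    only meaningful under identical protocols.
    """
    reports = []
    for p in paths:
        with open(p) as fh:
            reports.append(json.load(fh))
    ref = reports[0]["provenance"]["config"]["analysis"]
    for r in reports[1:]:
        other = r["provenance"]["config"]["analysis"]
        diffs = [k for k in _COMPARABLE_KEYS if other.get(k) != ref.get(k)]
        if diffs:
            raise ValueError(
                f"report {r['label']!r} used different tunables than "
                f"{reports[0]['label']!r}: {diffs}; re-run with matching settings"
            )
    rows = []
    for r in reports:
        row: dict = {"label": r["label"]}
        for group, vals in r["metrics"].items():
            for k, v in vals.items():
                row[f"{group}.{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
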