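"""Run configuration and pipeline orchestration.

A single human-editable YAML file drives the pipeline; every analysis is
independently toggleable (the analyses are independent given the
trajectory).  Defaults follow the standard analysis protocol: 0.8 nm contact
cutoff, 8 Å annular definition, 10-frame lifetime tolerance, 0.56 nm SASA
probe, x4 effective-time scaling on trajectory ingest, region boundaries at
3.0/4.0 nm.

Outputs are one TSV per analysis (header comments carry the parameters) plus
a machine-readable ``manifest.json`` with all parameters, seeds and the
package version — enough to reproduce every output bit-exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .model import Trajectory
from .io import read_structure, read_trajectory
from .synth import SyntheticSpec, build_trajectory

log = logging.getLogger("dropletmetrics")

ANALYSES = ("density", "order", "conformations", "diffusion",
            "contacts", "lifetimes", "rmsf", "sasa")


class ConfigError(ValueError):
    """Invalid run configuration (raised before any compute)."""


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "dropletmetrics_out"
    structure: str | None = None
    trajectory: str | None = None
    apply_time_scale: bool = True
    synthetic: dict = field(default_factory=dict)
    analyses: list[str] = field(default_factory=lambda: list(ANALYSES))
    # analysis parameters (defaults per the analysis protocol)
    cutoff_nm: float = 0.8
    annular_cutoff_nm: float = 0.8
    tolerance_frames: int = 10
    probe_nm: float = 0.56
    sasa_n_points: int = 960
    sasa_stride: int = 10
    bin_width_nm: float = 0.1
    region_boundaries: tuple[float, float] = (3.0, 4.0)
    lags_ns: list[float] | None = None
    min_jumps: int = 500
    wrap_guard_nm: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        r1, r2 = self.region_boundaries
        if not r1 < r2:
            raise ConfigError(f"region boundaries must satisfy r1 < r2, got {r1} >= {r2}")
        for a in self.analyses:
            if a not in ANALYSES:
                raise ConfigError(f"unknown analysis {a!r}; choose from {ANALYSES}")
        if self.cutoff_nm <= 0 or self.annular_cutoff_nm <= 0 or self.probe_nm <= 0:
            raise ConfigError("cutoffs and probe radius must be > 0")
        if self.tolerance_frames < 0:
            raise ConfigError("tolerance_frames must be >= 0")
        if self.bin_width_nm <= 0:
            raise ConfigError("bin_width_nm must be > 0")
        if (self.structure is None) != (self.trajectory is None):
            raise ConfigError("provide both structure and trajectory, or neither "
                              "(synthetic input)")


def _load_trajectory(cfg: RunConfig) -> Trajectory:
    if cfg.structure is not None:
        top, _ = read_structure(cfg.structure)
        traj = read_trajectory(top, cfg.trajectory,
                               apply_time_scale=cfg.apply_time_scale)
    else:
        spec = SyntheticSpec(**{**cfg.synthetic, "seed": cfg.synthetic.get("seed", cfg.seed)})
        traj = build_trajectory(spec)
    traj.check_wrap(cfg.wrap_guard_nm)
    return traj


def _write_tsv(df, path: Path, cfg: RunConfig, analysis: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dropletmetrics {__version__} analysis={analysis} "
                 f"seed={cfg.seed}\n")
        fh.write(f"# cutoff_nm={cfg.cutoff_nm} annular_cutoff_nm={cfg.annular_cutoff_nm} "
                 f"tolerance_frames={cfg.tolerance_frames} probe_nm={cfg.probe_nm} "
                 f"bin_width_nm={cfg.bin_width_nm} "
                 f"region_boundaries={list(cfg.region_boundaries)}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the selected analyses; return {analysis: output path}.

    Any stage error aborts with the stage name; outputs of completed stages
    are retained on disk.
    """
    from . import contacts as C
    from . import diffusion as D
    from . import orientation as O
    from . import radial as R
    from . import sasa as S
    import pandas as pd

    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    traj = _load_trajectory(config)
    log.info("loaded trajectory: %d frames, %d beads, %.3f ns/frame",
             traj.n_frames, traj.topology.n_beads,
             traj.dt_ns if traj.n_frames > 1 else float("nan"))

    species_present = [sp for sp in ("POPC", "PPC", "CHOL", "CE", "TG")
                       if traj.topology.molecules_of(sp).size]
    written: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            if name in config.analyses:
                t = time.time()
                try:
                    df = fn()
                except Exception as exc:
                    raise RuntimeError(f"analysis stage {name!r} failed: {exc}") from exc
                p = out / f"{name}.tsv"
                _write_tsv(df, p, config, name)
                written[name] = p
                log.info("stage %s: %.2f s -> %s", name, time.time() - t, p)
            return fn
        return deco

    @stage("density")
    def _density():
        prof = R.radial_density(traj, species_present, config.bin_width_nm)
        return prof.to_frame()

    @stage("order")
    def _order():
        from .synth import DEFAULT_AXES
        frames = []
        for sp in ("CHOL", "CE"):
            if sp in species_present:
                prof = O.order_parameter_profile(
                    traj, O.AxisDefinition(sp, *DEFAULT_AXES[sp]), config.bin_width_nm)
                df = prof.to_frame()
                df.insert(0, "species", sp)
                frames.append(df)
        return pd.concat(frames, ignore_index=True)

    @stage("conformations")
    def _conformations():
        cmap = O.conformation_map(traj, boundaries=config.region_boundaries)
        return cmap.to_frame()

    @stage("diffusion")
    def _diffusion():
        lags = config.lags_ns or D.default_lag_grid(traj)
        rows = []
        for sp in species_present:
            curve = D.diffusion_vs_lag(traj, sp, lags, min_jumps=config.min_jumps)
            final = curve.fits[-1]
            rows.append((sp, final.dimension, final.D,
                         2 * final.dimension * final.D, curve.plateau))
        return pd.DataFrame(rows, columns=["species", "dimension", "D_nm2_per_ns",
                                           "D_scaled_2dD", "plateau"])

    @stage("contacts")
    def _contacts():
        rows = []
        for sp in species_present:
            rec = C.annular_states(traj, sp, config.annular_cutoff_nm)
            count, frac = C.annular_summary(rec)
            rows.append((sp, rec.n_lipids, count, frac))
        return pd.DataFrame(rows, columns=["species", "n_molecules",
                                           "mean_annular_count", "annular_fraction"])

    @stage("lifetimes")
    def _lifetimes():
        rows = []
        for sp in species_present:
            rec = C.annular_states(traj, sp, config.annular_cutoff_nm)
            st = C.contact_lifetimes(rec, tolerance_frames=config.tolerance_frames)
            rows.append((sp, st.mean_on_ns, st.mean_off_ns,
                         len(st.on_dwells_ns), len(st.off_dwells_ns),
                         len(st.censored_on_ns) + len(st.censored_off_ns)))
        return pd.DataFrame(rows, columns=["species", "mean_contact_ns",
                                           "mean_noncontact_ns", "n_on", "n_off",
                                           "n_censored"])

    @stage("rmsf")
    def _rmsf():
        frames = []
        for ch, df in C.rmsf(traj).items():
            df = df.copy()
            df.insert(0, "chain", ch)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    @stage("sasa")
    def _sasa():
        mean, _ = S.sasa_timeseries(traj, stride=config.sasa_stride,
                                    probe_nm=config.probe_nm,
                                    n_points=config.sasa_n_points)
        tot = mean.total_nm2
        return pd.DataFrame([
            ("total", tot, 100.0),
            ("hydrophobic", mean.hydrophobic_nm2, 100 * mean.hydrophobic_nm2 / tot),
            ("hydrophilic", mean.hydrophilic_nm2, 100 * mean.hydrophilic_nm2 / tot),
        ], columns=["class", "sasa_nm2", "pct_of_total"])

    manifest = {
        "package": "dropletmetrics",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_frames": traj.n_frames,
        "n_beads": traj.topology.n_beads,
        "outputs": {k: str(v) for k, v in written.items()},
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = out / "manifest.json"
    return written
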