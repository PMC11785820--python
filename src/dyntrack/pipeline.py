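"""Orchestration: trajectory file I/O, run configuration, end-to-end runs.

A run is driven by a :class:`RunConfig` (YAML-serializable) selecting any
subset of the stages

    simulate -> segment -> phi (motor counting) -> steps (dwell kinetics,
    Arrhenius) -> cycle (chemomechanical predictions)

Each stage writes its tables under the output directory through the
declared text formats, and the collected numbers go into a
:class:`RunReport` (JSON structured form + human-readable text render).
Every stochastic stage derives its seed from the config, and the config
hash is recorded in the report so reruns are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cyclesim, motorcount, segment as segmod, stepkin, trajsim
from .trajsim import MotorStepModel, Trajectory

__all__ = [
    "RunConfig",
    "RunReport",
    "read_trajectory",
    "write_trajectory",
    "run_pipeline",
    "render_report",
    "demo_config",
    "__version__",
]

__version__ = "0.1.0"

log = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ["frame", "t_s", "x_nm", "y_nm", "photons"]

#: metadata keys serialized with trajectory files (arrays are not persisted)
_SCALAR_META = ("dt_s", "temperature_C", "seed", "n_motors", "localization_sd_nm",
                "dwell_rate_s")


# ---------------------------------------------------------------------------
# Trajectory file I/O
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path: "str | Path", sep: str = "\t") -> Path:
    """Write the delimited-text trajectory format.

    ``#``-prefixed ``key=value`` metadata lines, then a header line
    ``frame t_s x_nm y_nm photons`` and one row per frame.
    """
    path = Path(path)
    lines = []
    for key in _SCALAR_META:
        if key in traj.meta and traj.meta[key] is not None:
            lines.append(f"# {key}={traj.meta[key]}")
    lines.append(sep.join(TRAJECTORY_COLUMNS))
    for i in range(len(traj)):
        lines.append(sep.join([
            str(int(traj.frame[i])),
            f"{traj.t_s[i]:.6f}",
            f"{traj.x_nm[i]:.4f}",
            f"{traj.y_nm[i]:.4f}",
            f"{traj.photons[i]:.1f}",
        ]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trajectory(path: "str | Path", sep: str = "\t") -> Trajectory:
    """Read the delimited-text trajectory format written by
    :func:`write_trajectory`, with line-numbered diagnostics on bad input."""
    path = Path(path)
    meta: dict = {}
    header_line = None
    data_start = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, value = body.split("=", 1)
                    meta[key.strip()] = _parse_meta_value(value.strip())
                continue
            header_line = line
            data_start = lineno
            break
    if header_line is None:
        raise ValueError(f"{path}: no header line found")
    columns = header_line.split(sep)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in columns]
    if missing:
        raise ValueError(
            f"{path}:{data_start}: header is missing required column(s) "
            f"{', '.join(missing)}; expected {' '.join(TRAJECTORY_COLUMNS)}"
        )
    df = pd.read_csv(path, sep=sep, comment="#", header=0)
    t = df["t_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if len(bad):
        raise ValueError(
            f"{path}: time is non-monotone at data row {int(bad[0]) + 2} "
            f"(t={t[bad[0] + 1]} after t={t[bad[0]]})"
        )
    return Trajectory(
        frame=df["frame"].to_numpy(dtype=int),
        t_s=t,
        x_nm=df["x_nm"].to_numpy(dtype=float),
        y_nm=df["y_nm"].to_numpy(dtype=float),
        photons=df["photons"].to_numpy(dtype=float),
        meta=meta,
    )


def _parse_meta_value(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


# ---------------------------------------------------------------------------
# Configuration and report
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``motor_cohort`` lists (n_motors, n_segments) to simulate for the phi
    analysis; ``step_traces`` lists per-temperature stepping-trace specs
    (temperature_C, dwell_rate_s, n_steps, frame_interval_s, noise_sd_nm).
    """

    stages: tuple[str, ...] = ("simulate", "segment", "phi", "steps", "cycle")
    seed: int = 0
    output_dir: str = "dyntrack_run"
    input_trajectories: tuple[str, ...] = ()
    # simulator calibration
    step_mean_nm: float = 8.0
    step_variance_nm2: float = 96.0
    step_rate_s: float = 150.0
    localization_sd_nm: float = 2.0
    frame_interval_s: float = 0.01
    segment_duration_s: float = 60.0
    motor_cohort: tuple[tuple[int, int], ...] = ((1, 8), (2, 8), (3, 8))
    # phi analysis
    tau_grid_s: tuple[float, ...] = tuple(motorcount.default_tau_grid().tolist())
    tau_min_s: float = 0.12
    flatness_tol: float = 0.1
    # segmentation gates
    min_segment_duration_s: float = 1.0
    max_velocity_cv: float = 0.3
    # stepping kinetics
    step_traces: tuple[dict, ...] = (
        {"temperature_C": 22.0, "dwell_rate_s": 13.9, "n_steps": 283,
         "frame_interval_s": 0.0025, "noise_sd_nm": 2.0},
        {"temperature_C": 30.0, "dwell_rate_s": 56.1, "n_steps": 278,
         "frame_interval_s": 0.0025, "noise_sd_nm": 2.0},
        {"temperature_C": 37.0, "dwell_rate_s": 97.1, "n_steps": 920,
         "frame_interval_s": 0.001, "noise_sd_nm": 1.5},
    )
    min_step_nm: float = 4.0
    # stepping traces emulate the resolved single-motor mode (8-nm steps);
    # the 4-nm half-lattice components sit below the noise-exclusion floor
    step_trace_variance_nm2: float = 0.0
    # cycle parameters
    k_mt_per_um_s: float = 0.29
    atp_um: float = 3000.0
    k_pi_s: float = 97.1
    k_fast_s: float = 5000.0

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        for key in ("stages", "input_trajectories", "tau_grid_s"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "motor_cohort" in kwargs:
            kwargs["motor_cohort"] = tuple(tuple(x) for x in kwargs["motor_cohort"])
        if "step_traces" in kwargs:
            kwargs["step_traces"] = tuple(dict(x) for x in kwargs["step_traces"])
        return cls(**kwargs)

    def to_yaml(self, path: "str | Path") -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output path is excluded:
        the same analysis written elsewhere is the same analysis)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Structured per-stage outputs with provenance."""

    config_hash: str
    seed: int
    version: str = __version__
    phi: dict = field(default_factory=dict)
    motors: dict = field(default_factory=dict)
    dwell_fits: list = field(default_factory=list)
    arrhenius: dict = field(default_factory=dict)
    cycle: dict = field(default_factory=dict)
    files: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, data: dict) -> "RunReport":
        return cls(**data)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, outdir: Path, report: RunReport) -> list[Trajectory]:
    model = MotorStepModel.from_moments(
        config.step_mean_nm, config.step_variance_nm2, config.step_rate_s
    )
    ss = np.random.SeedSequence(config.seed)
    trajectories = []
    idx = 0
    for n_motors, n_segments in config.motor_cohort:
        for _ in range(n_segments):
            sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            cfg = trajsim.CargoConfig(
                n_motors=n_motors,
                localization_sd_nm=config.localization_sd_nm,
                frame_interval_s=config.frame_interval_s,
                duration_s=config.segment_duration_s,
                states=(trajsim.MotionState(
                    "retrograde",
                    velocity_nm_s=config.step_rate_s * config.step_mean_nm,
                ),),
                initial_state=0,
                seed=sub,
            )
            traj = trajsim.simulate_cargo_trajectory(model, cfg)
            path = write_trajectory(traj, outdir / f"traj_{idx:03d}_n{n_motors}.tsv")
            report.files.append(str(path))
            trajectories.append(traj)
            idx += 1
    return trajectories


def _stage_phi(config: RunConfig, outdir: Path, report: RunReport,
               trajectories: list[Trajectory]) -> None:
    tau_grid = np.asarray(config.tau_grid_s)
    rows = []
    asymptotes = []
    non_converged = []
    for i, traj in enumerate(trajectories):
        seg_id = f"seg_{i:03d}"
        stats = motorcount.displacement_stats(traj.x_nm, tau_grid, dt_s=traj.dt_s)
        if not stats:
            continue
        curve = motorcount.phi_curve(
            stats, noise_sd_nm=traj.meta.get("localization_sd_nm"), segment_id=seg_id
        )
        phi_inf, converged = motorcount.phi_asymptote(
            curve, tau_min_s=config.tau_min_s, flatness_tol=config.flatness_tol
        )
        for st, phi in zip(curve.stats, curve.phi_inv_nm):
            rows.append((seg_id, st.tau_s, st.mu_nm, st.s2_nm2, phi, st.n_pairs))
        if converged:
            asymptotes.append((seg_id, phi_inf, traj.meta.get("n_motors")))
        else:
            non_converged.append(seg_id)
    df = pd.DataFrame(rows, columns=["segment_id", "tau_s", "mu_nm", "s2_nm2",
                                     "phi_inv_nm", "n_pairs"])
    path = outdir / "phi_curves.tsv"
    df.to_csv(path, sep="\t", index=False)
    report.files.append(str(path))
    report.phi = {
        "asymptotes_inv_nm": [float(round(a, 6)) for _, a, _ in asymptotes],
        "segment_ids": [sid for sid, _, _ in asymptotes],
        "true_n_motors": [n for _, _, n in asymptotes],
        "non_converged_segments": non_converged,
        "fraction_converged": (
            len(asymptotes) / (len(asymptotes) + len(non_converged))
            if (asymptotes or non_converged) else None
        ),
    }
    if len(asymptotes) >= 4:
        values = np.array([a for _, a, _ in asymptotes])
        result = motorcount.motor_count_summary(values, seed=config.seed)
        report.motors = {
            "centers_inv_nm": [float(round(c, 6)) for c in result.centers_inv_nm],
            "phi1_inv_nm": float(round(result.phi1_inv_nm, 6)),
            "per_segment_n": result.motor_numbers.tolist(),
            "mean_n": round(result.mean_n, 4),
            "se_n": round(result.se_n, 4),
            "histogram": {str(k): v for k, v in result.histogram().items()},
        }


def _stage_steps(config: RunConfig, outdir: Path, report: RunReport) -> None:
    model = MotorStepModel.from_moments(
        config.step_mean_nm, config.step_trace_variance_nm2, config.step_rate_s
    )
    arr_pairs = []
    for j, spec in enumerate(config.step_traces):
        trace = trajsim.simulate_step_trace(
            model,
            dwell_rate_s=spec["dwell_rate_s"],
            n_steps=int(spec["n_steps"]),
            noise_sd_nm=spec["noise_sd_nm"],
            frame_interval_s=spec["frame_interval_s"],
            seed=config.seed + 1000 + j,
            temperature_c=spec["temperature_C"],
        )
        tpath = write_trajectory(trace, outdir / f"steps_{spec['temperature_C']:.0f}C.tsv")
        report.files.append(str(tpath))
        fit = stepkin.find_steps(trace, min_step_nm=config.min_step_nm)
        step_df = pd.DataFrame({
            "step_index": np.arange(fit.n_steps),
            "frame_time_s": fit.boundaries * spec["frame_interval_s"],
            "level_nm": fit.levels_nm[1:],
            "step_nm": fit.step_sizes_nm,
        })
        spath = outdir / f"stepfit_{spec['temperature_C']:.0f}C.tsv"
        step_df.to_csv(spath, sep="\t", index=False)
        report.files.append(str(spath))
        dwells = stepkin.dwell_times(fit, spec["frame_interval_s"])
        dfit = stepkin.fit_dwell_mle(dwells, "erlang2")
        rnd = stepkin.randomness(dwells, seed=config.seed + 2000 + j)
        report.dwell_fits.append({
            "temperature_C": spec["temperature_C"],
            "true_rate_s": spec["dwell_rate_s"],
            "k_s": round(dfit.rate_s, 4),
            "se_k_s": round(dfit.se_rate_s, 4),
            "n_dwells": dfit.n,
            "mean_dwell_ms": round(1e3 * 2.0 / dfit.rate_s, 4),
            "randomness_r": round(rnd.r, 4),
            "n_min": round(rnd.n_min, 4),
            "n_steps_found": fit.n_steps,
        })
        arr_pairs.append((spec["temperature_C"], dfit.rate_s, dfit.se_rate_s))
    if len(arr_pairs) >= 2:
        arr = stepkin.arrhenius_fit(arr_pairs)
        report.arrhenius = {
            "ea_kcal_mol": round(arr.ea_kcal_mol, 4),
            "se_ea_kcal_mol": round(arr.se_ea_kcal_mol, 4),
            "prefactor_s": arr.prefactor_s,
            "pairs_T_K_k_s": [[round(t, 2), round(k, 4)] for t, k in arr.pairs],
        }


def _stage_cycle(config: RunConfig, outdir: Path, report: RunReport) -> None:
    grid = np.logspace(0, 4, 25)
    cycle_out = {}
    for scheme in ("two_ATP", "one_ATP"):
        model = cyclesim.build_cycle(
            scheme,
            k_mt_per_um_s=config.k_mt_per_um_s,
            atp_um=config.atp_um,
            k_pi_s=config.k_pi_s,
            k_hyd_s=config.k_fast_s,
            k_adp_s=config.k_fast_s,
            instantaneous_fast=True,
        )
        resp = cyclesim.velocity_vs_atp(model, grid)
        df = pd.DataFrame({
            "S_uM": resp.atp_um,
            "mean_dwell_s": resp.mean_dwell_s,
            "v_nm_s": resp.velocity_nm_s,
            "n_min": resp.n_min,
        })
        path = outdir / f"cycle_{scheme}.tsv"
        df.to_csv(path, sep="\t", index=False)
        report.files.append(str(path))
        stats = cyclesim.closed_form_dwell_stats(model)
        cycle_out[scheme] = {
            "binding_rate_s": round(model.binding_rate_s, 4),
            "mean_dwell_ms_at_default_atp": round(1e3 * stats.mean_s, 4),
            "n_min_at_default_atp": round(stats.n_min, 4),
            "vmax_nm_s": round(resp.vmax_nm_s, 4),
            "km_um": round(resp.km_um, 4),
            "n_hill": round(resp.n_hill, 4),
            "n_min_high_atp": round(float(resp.n_min[-1]), 4),
            "n_min_low_atp": round(float(resp.n_min[0]), 4),
            "n_min_max": round(float(resp.n_min.max()), 4),
        }
    report.cycle = cycle_out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the selected stages; persists tables; returns the report.

    A stage failure aborts the run with a stage-tagged error; partial
    outputs written so far are retained in the output directory.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash, seed=config.seed)
    config.to_yaml(outdir / "config.yaml")
    trajectories: list[Trajectory] = []
    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                trajectories = _stage_simulate(config, outdir, report)
            elif stage == "segment":
                # ingest external inputs here when provided
                for p in config.input_trajectories:
                    trajectories.append(read_trajectory(p))
            elif stage == "phi":
                _stage_phi(config, outdir, report, trajectories)
            elif stage == "steps":
                _stage_steps(config, outdir, report)
            elif stage == "cycle":
                _stage_cycle(config, outdir, report)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
    render_report(report, outdir / "report.json", fmt="structured")
    render_report(report, outdir / "report.txt", fmt="text")
    return report


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def render_report(report: RunReport, path: "str | Path", fmt: str = "structured") -> Path:
    """Write the report: ``structured`` (JSON, parses back losslessly) or
    ``text`` (human-readable, every quantity with units)."""
    path = Path(path)
    if fmt == "structured":
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
        return path
    if fmt != "text":
        raise ValueError(f"unknown report format {fmt!r}")
    lines = [
        "dyntrack run report",
        f"  version: {report.version}",
        f"  config hash: {report.config_hash}",
        f"  seed: {report.seed}",
    ]
    if report.phi:
        lines.append("phi analysis:")
        lines.append(f"  converged asymptotes [1/nm]: "
                     f"{['%.3f' % a for a in report.phi['asymptotes_inv_nm']]}")
        if report.phi.get("non_converged_segments"):
            lines.append(f"  non-converged segments (no asymptote): "
                         f"{report.phi['non_converged_segments']}")
        if report.phi.get("fraction_converged") is not None:
            lines.append(f"  fraction converged: {report.phi['fraction_converged']:.2f}")
    if report.motors:
        m = report.motors
        lines.append("motor counting:")
        lines.append(f"  cluster centers [1/nm]: {m['centers_inv_nm']}")
        lines.append(f"  quantum phi_1 [1/nm]: {m['phi1_inv_nm']}")
        lines.append(f"  mean motors n: {m['mean_n']} +/- {m['se_n']} (SE)")
    for d in report.dwell_fits:
        lines.append(
            f"dwell fit at {d['temperature_C']} C: k = {d['k_s']} +/- {d['se_k_s']} 1/s "
            f"(n = {d['n_dwells']} dwells), mean dwell {d['mean_dwell_ms']} ms, "
            f"n_min = {d['n_min']}"
        )
    if report.arrhenius:
        a = report.arrhenius
        lines.append(
            f"Arrhenius: Ea = {a['ea_kcal_mol']} +/- {a['se_ea_kcal_mol']} kcal/mol"
        )
    for scheme, c in report.cycle.items():
        lines.append(
            f"cycle {scheme}: binding rate {c['binding_rate_s']} 1/s, "
            f"Vmax {c['vmax_nm_s']} nm/s, K {c['km_um']} uM, "
            f"Hill n = {c['n_hill']}, n_min(high ATP) = {c['n_min_high_atp']}, "
            f"n_min(max) = {c['n_min_max']}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def demo_config(output_dir: "str | Path" = "dyntrack_demo", seed: int = 0) -> RunConfig:
    """The packaged demo: three-temperature stepping fixtures and a 1-3
    motor cohort, sized to run in seconds."""
    return RunConfig(seed=seed, output_dir=str(output_dir))
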