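"""Reproducible workflows tying the sampler and analysis modules together.

The central workflow mirrors the method's loop on a desk-scale system:
sample under the current canonical-density estimate, update and GA-refine
the estimate, check the per-zone convergence diagnostic, and finally assign
canonical weights to every stored snapshot.  :func:`converge_double_well`
runs that loop on the 1-D double well, for which quadrature ground truth is
available, and reports weighted observables against it.

:func:`validate_config` turns a structured (YAML) config document into a
:class:`RunConfig` with itemized error reporting; :func:`run_pipeline`
dispatches the CLI commands.  Identical config + seed give byte-identical
outputs (floating-point formatting pinned in the writers).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

import flycast
from flycast.binding_analysis import (
    WeightedEnsemble,
    density_field,
    native_contact_profile,
    residue_contact_pmf,
    rmsd_distributions,
    write_dx,
)
from flycast.qcano_estimator import (
    E_LOCAL_THRESHOLD,
    ConvergenceReport,
    QSurface,
    e_local,
    ga_refine,
    physical_bin_edges,
    snapshot_weights,
    update_q,
    zone_bin_histograms,
)
from flycast.rc_zones import ZoneAxis, ZoneGrid
from flycast.structure_io import read_pdb, write_pdb
from flycast.synthetic_models import (
    DoubleWell1D,
    LangevinBackend,
    SyntheticEnsembleSpec,
    boltzmann_marginal,
    generate_binding_ensemble,
)
from flycast.vcmd_engine import (
    EngineConfig,
    Snapshot,
    read_snapshots_tsv,
    run_iteration,
    select_seeds,
    write_snapshots_tsv,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "validate_config",
    "run_pipeline",
    "converge_double_well",
    "RecoveryResult",
    "DEFAULT_CONFIG",
]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised with an itemized list of configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


#: Documented defaults for the desk-scale double-well study.
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "output_dir": "out",
    "toy": {"kind": "double_well", "barrier_height": 1.8, "half_separation": 1.0,
            "domain_halfwidth": 2.5, "temperature": 300.0},
    "zones": {"lower": -2.5, "upper": 2.5, "count": 8, "overlap_fraction": 0.75, "nbins": 8},
    "engine": {"runs_per_iteration": 256, "steps_per_run": 16000,
               "transition_interval_steps": 600, "snapshot_interval_steps": 600,
               "restraint_spring": 25.0, "temperature": 300.0, "time_step": 2.0},
    "backend": {"dt": 0.005, "friction": 1.0},
    "sampling": {"max_iterations": 18, "min_iterations": 12},
    "synthetic": {"n_snapshots": 20000},
    "analysis": {"cube_edge": 3.0, "contact_cutoff": 5.0, "temperature": 300.0},
    "log_level": "INFO",
}


@dataclass
class RunConfig:
    """Validated, fully defaulted run configuration."""

    seed: int
    output_dir: Path
    toy: dict[str, Any]
    zones: dict[str, Any]
    engine: dict[str, Any]
    backend: dict[str, Any]
    sampling: dict[str, Any]
    synthetic: dict[str, Any]
    analysis: dict[str, Any]
    log_level: str = "INFO"
    rcs: list[dict[str, Any]] | None = None

    def effective(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        return d


def _merge(defaults: Mapping[str, Any], given: Mapping[str, Any], prefix: str, problems: list[str]) -> dict[str, Any]:
    out = dict(defaults)
    for key, value in given.items():
        if key not in defaults:
            problems.append(f"unknown key {prefix}{key!r}")
            continue
        out[key] = value
    return out


def validate_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Parse and cross-check a config document, filling documented defaults.

    Problems (unknown keys, missing seed, zone/RC dimensionality mismatch)
    are collected and raised together as a :class:`ConfigError`.  The
    effective values are echoed to the log.
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(["config document must be a mapping"])
    problems: list[str] = []
    known_top = set(DEFAULT_CONFIG) | {"rcs"}
    for key in raw:
        if key not in known_top:
            problems.append(f"unknown key {key!r}")
    if "seed" not in raw:
        problems.append("'seed' is mandatory for any stochastic command")
    sections = {}
    for name in ("toy", "zones", "engine", "backend", "sampling", "synthetic", "analysis"):
        sections[name] = _merge(DEFAULT_CONFIG[name], raw.get(name, {}) or {}, f"{name}.", problems)
    rcs = raw.get("rcs")
    n_axes = 1  # the bundled toy studies are 1-D in RC space
    if rcs is not None:
        if not isinstance(rcs, list) or not rcs:
            problems.append("'rcs' must be a non-empty list of RC definitions")
        elif len(rcs) != n_axes:
            problems.append(
                f"dimensionality mismatch: {len(rcs)} RCs declared but {n_axes} zone axes configured"
            )
    if problems:
        raise ConfigError(problems)
    cfg = RunConfig(
        seed=int(raw["seed"]),
        output_dir=Path(raw.get("output_dir", DEFAULT_CONFIG["output_dir"])),
        toy=sections["toy"],
        zones=sections["zones"],
        engine=sections["engine"],
        backend=sections["backend"],
        sampling=sections["sampling"],
        synthetic=sections["synthetic"],
        analysis=sections["analysis"],
        log_level=str(raw.get("log_level", DEFAULT_CONFIG["log_level"])),
        rcs=rcs,
    )
    log.info("effective configuration: %s", json.dumps(cfg.effective(), default=str, sort_keys=True))
    return cfg


# ---------------------------------------------------------------------------
# Canonical-recovery workflow on the double well


@dataclass
class RecoveryResult:
    """Everything the double-well convergence loop produced."""

    potential: DoubleWell1D
    grid: ZoneGrid
    q: QSurface
    reports: list[ConvergenceReport]
    converged: bool
    iterations_run: int
    snapshots: list[Snapshot]
    weights: np.ndarray
    bin_edges: np.ndarray
    weighted_hist: np.ndarray
    quadrature_hist: np.ndarray
    l1_distance: float
    mean_x: float
    mean_x2: float
    se_x: float
    se_x2: float
    quad_mean_x: float
    quad_mean_x2: float


def _initial_seeds(grid: ZoneGrid, n: int, rng: np.random.Generator) -> list[Snapshot]:
    """Scatter seeds round-robin across zones, uniformly within each box."""
    zones = list(grid.zones())
    seeds = []
    for i in range(n):
        zone = zones[i % len(zones)]
        lo, hi = grid.zone_box(zone)
        x = rng.uniform(lo, hi)
        seeds.append(Snapshot(iteration=0, run=i, step=0, lam=x, zone=zone, state=x))
    return seeds


def _weighted_block_se(
    snapshots: list[Snapshot], weights: np.ndarray, func
) -> tuple[float, float]:
    """Weighted mean of func(x) with a run-block standard error.

    Blocks are (iteration, run) trajectories, which are mutually independent
    by construction of the per-run RNG streams; blocking absorbs the
    within-run autocorrelation of snapshots.
    """
    vals = np.array([func(np.atleast_1d(s.lam)[0]) for s in snapshots])
    keys = np.array([(s.iteration, s.run) for s in snapshots])
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)
    n_blocks = len(uniq)
    bw = np.zeros(n_blocks)
    bwx = np.zeros(n_blocks)
    np.add.at(bw, inv, weights)
    np.add.at(bwx, inv, weights * vals)
    total = bw.sum()
    mean = bwx.sum() / total
    block_means = np.where(bw > 0, bwx / np.where(bw > 0, bw, 1), 0.0)
    wfrac = bw / total
    se2 = np.sum(wfrac**2 * (block_means - mean) ** 2)
    if n_blocks > 1:
        se2 *= n_blocks / (n_blocks - 1)
    return float(mean), float(np.sqrt(se2))


def _estimator_moment_se(
    q: QSurface,
    cumulative: dict[tuple[int, ...], np.ndarray],
    edges: np.ndarray,
    rng: np.random.Generator,
    replicas: int = 16,
) -> tuple[float, float]:
    """Bootstrap SE of ⟨x⟩ and ⟨x²⟩ due to density-estimation noise.

    Per replica the pooled per-zone counts are redrawn multinomially,
    re-estimated (update + stitch), and the moments recomputed from the
    resulting RC marginal.
    """
    centers = (edges[:-1] + edges[1:]) / 2
    base = QSurface.uniform(q.grid, q.nbins)
    m1, m2 = [], []
    for _ in range(replicas):
        hists = {}
        for zone, obs in cumulative.items():
            total = int(obs.sum())
            if total == 0:
                hists[zone] = obs
                continue
            p = (obs + 0.5) / (obs + 0.5).sum()
            hists[zone] = rng.multinomial(total, p.ravel()).reshape(obs.shape).astype(float)
        qb = update_q(base, hists)
        dens = np.array([qb.density_at([c]) for c in centers])
        dens = dens / dens.sum()
        m1.append(float((dens * centers).sum()))
        m2.append(float((dens * centers**2).sum()))
    return float(np.std(m1, ddof=1)), float(np.std(m2, ddof=1))


def converge_double_well(
    seed: int = 0,
    config: RunConfig | None = None,
    observable_bins: int = 40,
) -> RecoveryResult:
    """Run the full sample → update → refine → converge → reweight loop on
    the 1-D double well and compare weighted observables with quadrature.

    Iterations continue until every zone satisfies the convergence gate
    ``e_local < 0.25`` (after at least ``min_iterations``) or the iteration
    cap is reached.  All snapshots from all iterations are then reweighted
    with the final density estimate.
    """
    cfg = config or validate_config({"seed": seed})
    potential = DoubleWell1D(
        barrier_height=float(cfg.toy["barrier_height"]),
        half_separation=float(cfg.toy["half_separation"]),
        domain_halfwidth=float(cfg.toy["domain_halfwidth"]),
    )
    z = cfg.zones
    grid = ZoneGrid(
        (ZoneAxis.uniform("x", float(z["lower"]), float(z["upper"]), int(z["count"]),
                          float(z["overlap_fraction"])),)
    )
    engine = EngineConfig(
        time_step=float(cfg.engine["time_step"]),
        transition_interval_steps=int(cfg.engine["transition_interval_steps"]),
        temperature=float(cfg.engine["temperature"]),
        restraint_spring=float(cfg.engine["restraint_spring"]),
        runs_per_iteration=int(cfg.engine["runs_per_iteration"]),
        steps_per_run=int(cfg.engine["steps_per_run"]),
        snapshot_interval_steps=int(cfg.engine["snapshot_interval_steps"]),
        rng_seed=int(seed),
    )
    backend = LangevinBackend(
        potential,
        dt=float(cfg.backend["dt"]),
        friction=float(cfg.backend["friction"]),
        temperature=float(cfg.engine["temperature"]),
    )
    rng = np.random.default_rng([int(seed), 977])
    q = QSurface.uniform(grid, nbins=int(z["nbins"]))
    seeds = _initial_seeds(grid, engine.runs_per_iteration, rng)
    all_snapshots: list[Snapshot] = []
    reports: list[ConvergenceReport] = []
    converged = False
    max_iter = int(cfg.sampling["max_iterations"])
    min_iter = int(cfg.sampling["min_iterations"])
    iteration = 0
    # Within-zone histograms estimate the zone-restricted canonical shape,
    # which does not depend on the density estimate the sampler ran under,
    # so counts pool across iterations: the estimate sharpens as data
    # accumulate and the convergence diagnostic measures real stabilization.
    cumulative: dict[tuple[int, ...], np.ndarray] | None = None
    for iteration in range(1, max_iter + 1):
        snaps, hist = run_iteration(engine, backend, q, grid, seeds, iteration=iteration)
        all_snapshots.extend(snaps)
        fresh = zone_bin_histograms(snaps, q)
        if cumulative is None:
            cumulative = fresh
        else:
            for zone in cumulative:
                cumulative[zone] = cumulative[zone] + fresh[zone]
        q_new = ga_refine(
            update_q(q, cumulative),
            rng=np.random.default_rng([int(seed), 31, iteration]),
        )
        report = e_local(q_new, q, iteration=iteration)
        reports.append(report)
        log.info(
            "iteration %d: %d/%d zones converged (max e_local %.3f)",
            iteration, report.converged_zones, len(report.e_local), max(report.e_local.values()),
        )
        q = q_new
        if iteration >= min_iter and report.all_converged:
            converged = True
            break
        seeds = select_seeds(snaps, hist, engine.runs_per_iteration, rng)

    weights = snapshot_weights(all_snapshots, q)

    # compare on the estimator's own physical binning so the L1 distance
    # measures estimator error, not resolution mismatch
    lo, hi = potential.domain
    edges = physical_bin_edges(q)[0]
    xs = np.array([np.atleast_1d(s.lam)[0] for s in all_snapshots])
    w_hist, _ = np.histogram(xs, bins=edges, weights=weights)
    w_hist = w_hist / w_hist.sum()
    quad = boltzmann_marginal(potential, edges, temperature=engine.temperature)
    l1 = float(np.abs(w_hist - quad).sum())

    fine = np.linspace(float(lo[0]), float(hi[0]), 4001)
    rt = 1.987204259e-3 * engine.temperature
    p = np.exp(-potential.energy(fine[:, None]) / rt)
    p /= np.trapezoid(p, fine)
    quad_mean_x = float(np.trapezoid(p * fine, fine))
    quad_mean_x2 = float(np.trapezoid(p * fine**2, fine))
    mean_x, se_x = _weighted_block_se(all_snapshots, weights, lambda x: x)
    mean_x2, se_x2 = _weighted_block_se(all_snapshots, weights, lambda x: x**2)
    # The block SE captures sampling noise only; the density estimate itself
    # (within-zone shapes + stitched zone scales) carries uncertainty that
    # propagates into the weighted observables.  Estimate it by parametric
    # bootstrap of the pooled per-zone histograms through the update/stitch,
    # and add it in quadrature.
    se_est_x, se_est_x2 = _estimator_moment_se(
        q, cumulative, edges, rng=np.random.default_rng([int(seed), 40709])
    )
    se_x = float(np.hypot(se_x, se_est_x))
    se_x2 = float(np.hypot(se_x2, se_est_x2))

    return RecoveryResult(
        potential=potential,
        grid=grid,
        q=q,
        reports=reports,
        converged=converged,
        iterations_run=iteration,
        snapshots=all_snapshots,
        weights=weights,
        bin_edges=edges,
        weighted_hist=w_hist,
        quadrature_hist=quad,
        l1_distance=l1,
        mean_x=mean_x,
        mean_x2=mean_x2,
        se_x=se_x,
        se_x2=se_x2,
        quad_mean_x=quad_mean_x,
        quad_mean_x2=quad_mean_x2,
    )


# ---------------------------------------------------------------------------
# Command dispatch


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _manifest(cfg: RunConfig, command: str, inputs: list[str], outputs: list[str]) -> str:
    payload = {
        "command": command,
        "seed": cfg.seed,
        "inputs": inputs,
        "outputs": outputs,
        "config": cfg.effective(),
        "flycast_version": flycast.__version__,
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    return json.dumps(payload, indent=2, sort_keys=True, default=str)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the '{producer}' command first"
        )
    return path


def _tail_groups(reference):
    """Per-residue tail atom groups, reconstructed from the reference by the
    bundled synthetic template's selection conventions (chain A = tail)."""
    from flycast.synthetic_models import TAIL_RESIDUES

    return [
        reference.select(f"{name}{num}", chain="A", res_numbers=[num])
        for num, name in TAIL_RESIDUES
    ]


def run_pipeline(config: RunConfig, command: str) -> dict[str, Path]:
    """Execute one pipeline command; returns the artifacts written.

    Commands mirror the method's loop: ``generate-toy`` (synthetic binding
    ensemble + ground truth), ``sample`` (the double-well convergence loop),
    ``estimate-q``, ``convergence``, ``reweight`` (file-level single steps),
    and ``analyze`` (binding statistics on a generated ensemble).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if command == "generate-toy":
        spec = SyntheticEnsembleSpec(
            n_snapshots=int(config.synthetic["n_snapshots"]), seed=config.seed
        )
        ensemble, truth = generate_binding_ensemble(spec)
        table, pdb = out / "ensemble.tsv", out / "ensemble.pdb"
        ensemble.to_files(table, pdb)
        write_pdb(ensemble.reference, out / "reference.pdb")
        truth_payload = {
            "n_snapshots": spec.n_snapshots,
            "seed": spec.seed,
            "pocket_weight": spec.pocket_weight,
            "pocket_sigma": spec.pocket_sigma,
            "shell_radius": list(spec.shell_radius),
            "kappa_inside": spec.kappa_inside,
            "kappa_outside": spec.kappa_outside,
            "tail_contact_prob": spec.tail_contact_prob.tolist(),
            "native_curves": [list(c) for c in spec.native_curves],
        }
        _atomic_write_text(out / "ground_truth.json", json.dumps(truth_payload, indent=2))
        artifacts = {"table": table, "structures": pdb, "reference": out / "reference.pdb",
                     "ground_truth": out / "ground_truth.json"}

    elif command == "sample":
        result = converge_double_well(config.seed, config)
        for i, s in enumerate(result.snapshots):
            s.weight = float(result.weights[i])
        write_snapshots_tsv(result.snapshots, out / "snapshots.tsv")
        result.grid.to_tsv(out / "zones.tsv")
        result.q.to_tsv(out / "qsurface.tsv")
        conv = pd.concat([r.to_frame() for r in result.reports], ignore_index=True)
        conv.to_csv(out / "convergence.tsv", sep="\t", index=False, float_format="%.12g")
        summary = {
            "converged": result.converged,
            "iterations_run": result.iterations_run,
            "l1_distance": result.l1_distance,
            "mean_x": result.mean_x,
            "mean_x2": result.mean_x2,
            "quad_mean_x": result.quad_mean_x,
            "quad_mean_x2": result.quad_mean_x2,
        }
        _atomic_write_text(out / "summary.json", json.dumps(summary, indent=2, sort_keys=True))
        artifacts = {name: out / f"{name}" for name in
                     ("snapshots.tsv", "zones.tsv", "qsurface.tsv", "convergence.tsv", "summary.json")}

    elif command == "estimate-q":
        snaps = read_snapshots_tsv(_require(out / "snapshots.tsv", "sample"))
        grid = ZoneGrid.from_tsv(_require(out / "zones.tsv", "sample"))
        q_prev = QSurface.from_tsv(_require(out / "qsurface.tsv", "sample"), grid)
        q = ga_refine(
            update_q(q_prev, zone_bin_histograms(snaps, q_prev)),
            rng=np.random.default_rng([config.seed, 31]),
        )
        q.to_tsv(out / "qsurface.tsv")
        artifacts = {"qsurface.tsv": out / "qsurface.tsv"}

    elif command == "convergence":
        snaps = read_snapshots_tsv(_require(out / "snapshots.tsv", "sample"))
        grid = ZoneGrid.from_tsv(_require(out / "zones.tsv", "sample"))
        q_prev = QSurface.from_tsv(_require(out / "qsurface.tsv", "sample"), grid)
        q_curr = ga_refine(
            update_q(q_prev, zone_bin_histograms(snaps, q_prev)),
            rng=np.random.default_rng([config.seed, 31]),
        )
        report = e_local(q_curr, q_prev)
        report.to_frame().to_csv(out / "convergence.tsv", sep="\t", index=False, float_format="%.12g")
        artifacts = {"convergence.tsv": out / "convergence.tsv"}

    elif command == "reweight":
        snaps = read_snapshots_tsv(_require(out / "snapshots.tsv", "sample"))
        grid = ZoneGrid.from_tsv(_require(out / "zones.tsv", "sample"))
        q = QSurface.from_tsv(_require(out / "qsurface.tsv", "sample"), grid)
        weights = snapshot_weights(snaps, q)
        for s, w in zip(snaps, weights):
            s.weight = float(w)
        write_snapshots_tsv(snaps, out / "snapshots.tsv")
        artifacts = {"snapshots.tsv": out / "snapshots.tsv"}

    elif command == "analyze":
        from flycast.synthetic_models import synthetic_anchors, synthetic_groups

        table = _require(out / "ensemble.tsv", "generate-toy")
        reference = read_pdb(_require(out / "reference.pdb", "generate-toy"))[0]
        groups = synthetic_groups(reference)
        anchors = synthetic_anchors(groups)
        ensemble = WeightedEnsemble.from_files(
            table, reference, groups["tm"], structures=out / "ensemble.pdb"
        )
        edge = float(config.analysis["cube_edge"])
        cutoff = float(config.analysis["contact_cutoff"])
        temperature = float(config.analysis["temperature"])
        rho = density_field(ensemble, groups["ligand"], edge=edge)
        write_dx(rho, out / "density_CMb.dx")
        tail_groups = _tail_groups(reference)
        pmf = residue_contact_pmf(
            ensemble, groups["ligand"], tail_groups, cutoff=cutoff, temperature=temperature
        )
        rows = []
        for k in range(pmf.values.shape[0]):
            for j, res in enumerate(pmf.meta["residues"]):
                rows.append({
                    "slice": k + 1, "residue": res,
                    "rho_cnt": f"{pmf.probabilities[k, j]:.12g}",
                    "pmf_kcal_mol": "" if not pmf.defined[k, j] else f"{pmf.values[k, j]:.12g}",
                })
        pd.DataFrame(rows).to_csv(out / "residue_contact_pmf.tsv", sep="\t", index=False)
        from flycast.synthetic_models import template_native_contacts

        profile = native_contact_profile(
            ensemble, list(template_native_contacts(groups, cutoff=cutoff)), groups["ligand"]
        )
        pd.DataFrame({
            "r_bb": profile.centers,
            "n_cnt": [f"{v:.12g}" if d else "" for v, d in zip(profile.mean, profile.defined)],
            "sd_cnt": [f"{v:.12g}" if d else "" for v, d in zip(profile.sd, profile.defined)],
            "occupancy": profile.occupancy.astype(int),
        }).to_csv(out / "native_contacts.tsv", sep="\t", index=False)
        dist = rmsd_distributions(ensemble, groups["ligand"])
        pd.DataFrame({
            "rmsd": dist.centers,
            "p_ddf": [f"{v:.12g}" for v in dist.p_ddf],
            "p_rdf": [f"{v:.12g}" for v in dist.p_rdf],
        }).to_csv(out / "rmsd_distributions.tsv", sep="\t", index=False)
        artifacts = {name: out / name for name in
                     ("density_CMb.dx", "residue_contact_pmf.tsv", "native_contacts.tsv",
                      "rmsd_distributions.tsv")}
    else:
        raise ValueError(f"unknown command {command!r}")

    manifest = _manifest(config, command, [], [str(p) for p in artifacts.values()])
    _atomic_write_text(out / f"manifest_{command.replace('-', '_')}.json", manifest)
    artifacts["manifest"] = out / f"manifest_{command.replace('-', '_')}.json"
    return artifacts
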