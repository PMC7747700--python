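"""Config-driven orchestration of the three analysis tracks.

A run config is one YAML document selecting a track (synth | ensemble |
trajectory | assay) plus inputs and parameters; defaults reproduce the
study settings (contact cutoff 4.5 A, contact fraction 0.75, source
residue 410, sink residue 534, top 1000 paths), so a near-empty config is
runnable.  Every reported number is also written to a stage output file
under the run's output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allosteric_network import (
    build_network,
    contact_fractions,
    path_histogram,
    suboptimal_paths,
)
from .assay_fits import CompetitionDataset, MeltCurve, fit_boltzmann, fit_ki
from .dynamics import correlation_matrix, rmsf
from .ensemble_io import (
    Ensemble,
    Selection,
    read_multimodel_pdb,
    read_xyz_table,
    write_multimodel_pdb,
    write_xyz_table,
)
from .errors import ConfigError
from .interactions import (
    AromaticRing,
    HBondCriterion,
    StackingCriterion,
    WaterNetworkSpec,
    edge_to_face_satisfied,
    hbond_satisfied,
    persistence,
    water_network_state,
)
from .synthetic_data import (
    CompetitionSpec,
    EnsembleSpec,
    MeltSpec,
    TrajectorySpec,
    make_competition_dataset,
    make_correlated_trajectory,
    make_interaction_ensemble,
    make_melt_curve,
)

logger = logging.getLogger(__name__)

TRACKS = ("synth", "ensemble", "trajectory", "assay")

DEFAULT_NETWORK = {"cutoff": 4.5, "fraction": 0.75, "source": 410, "sink": 534,
                   "k": 1000, "contact_mode": "heavy"}

#: Criteria matching the synthetic interaction ensemble's topology.
DEFAULT_CRITERIA = {
    "hbond": {
        "donor": {"resname": "LIG", "name": "O1"},
        "acceptor": {"resid": 345, "name": "SD"},
        "dmax": 3.5,
    },
    "stacking": {
        "ring1": {"resname": "LIG", "name": ["C11", "C12", "C13", "C14", "C15", "C16"]},
        "ring2": {"resid": 390, "name": ["CG", "ND1", "CD2", "CE1", "NE2"]},
        "angle_window": [60.0, 120.0],
        "centroid_dmax": 5.5,
    },
    "water_network": {
        "anchors": {"resid": 352, "name": "OG1"},
        "expected_count": 4,
        "link_dmax": 3.5,
    },
}


@dataclass
class RunConfig:
    track: str
    input: str | None = None
    criteria: dict = field(default_factory=lambda: dict(DEFAULT_CRITERIA))
    network: dict = field(default_factory=lambda: dict(DEFAULT_NETWORK))
    assay: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "allopath_out"
    raw: dict = field(default_factory=dict)


def validate(config_path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Validate a YAML run config, collecting (not fail-fast) all errors."""
    errors: list[str] = []
    try:
        raw = yaml.safe_load(Path(config_path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"config: unreadable ({exc})"]
    track = raw.get("track")
    if track not in TRACKS:
        errors.append(f"track: must be one of {TRACKS}, got {track!r}")
    inp = raw.get("input")
    if track in ("ensemble", "trajectory") and not inp:
        errors.append("input: required for ensemble/trajectory tracks")
    if inp and not Path(inp).exists():
        errors.append(f"input: file does not exist: {inp}")
    net = {**DEFAULT_NETWORK, **raw.get("network", {})}
    if not 0 < net["fraction"] <= 1:
        errors.append(f"network.fraction: must be in (0, 1], got {net['fraction']}")
    if net["cutoff"] <= 0:
        errors.append(f"network.cutoff: must be positive, got {net['cutoff']}")
    if int(net["k"]) < 1:
        errors.append(f"network.k: must be >= 1, got {net['k']}")
    assay = raw.get("assay", {})
    for key in ("fp_csv", "dsf_csv", "dsf_reference_csv"):
        p = assay.get(key)
        if p and not Path(p).exists():
            errors.append(f"assay.{key}: file does not exist: {p}")
    if track == "assay" and not (assay.get("fp_csv") or assay.get("dsf_csv")):
        errors.append("assay: needs fp_csv and/or dsf_csv")
    if errors:
        return None, errors
    criteria = raw.get("criteria") or dict(DEFAULT_CRITERIA)
    return (
        RunConfig(track=track, input=inp, criteria=criteria, network=net,
                  assay=assay, seed=int(raw.get("seed", 0)),
                  outdir=str(raw.get("outdir", "allopath_out")), raw=raw),
        [],
    )


# ---------------------------------------------------------------------------
# assay table I/O


def read_fp_csv(path: str | Path, probe_conc: float, probe_kd: float
                ) -> CompetitionDataset:
    """CSV with columns conc_M, rep1, rep2, ... (one row per dose)."""
    df = pd.read_csv(path)
    if "conc_M" not in df.columns:
        raise ConfigError(f"{path}: missing conc_M column")
    reps = [c for c in df.columns if c != "conc_M"]
    return CompetitionDataset(
        X=np.log10(df["conc_M"].to_numpy(float)),
        Y=df[reps].to_numpy(float),
        probe_conc=probe_conc,
        probe_Kd=probe_kd,
    )


def write_fp_csv(ds: CompetitionDataset, path: str | Path) -> None:
    out = pd.DataFrame({"conc_M": 10.0**ds.X})
    for r in range(ds.Y.shape[1]):
        out[f"rep{r + 1}"] = ds.Y[:, r]
    out.to_csv(path, index=False)


def read_dsf_csv(path: str | Path) -> list[MeltCurve]:
    """CSV with columns temp_C, well1, ..., optional blank (subtracted)."""
    df = pd.read_csv(path)
    if "temp_C" not in df.columns:
        raise ConfigError(f"{path}: missing temp_C column")
    T = df["temp_C"].to_numpy(float)
    blank = df["blank"].to_numpy(float) if "blank" in df.columns else None
    curves = []
    for col in df.columns:
        if col in ("temp_C", "blank"):
            continue
        c = MeltCurve(T=T, F=df[col].to_numpy(float))
        curves.append(c.subtract_blank(blank) if blank is not None else c)
    return curves


def write_dsf_csv(curves: dict[str, MeltCurve], path: str | Path) -> None:
    first = next(iter(curves.values()))
    out = pd.DataFrame({"temp_C": first.T})
    for name, c in curves.items():
        out[name] = c.F
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# tracks


def _sel(d: dict) -> Selection:
    return Selection(**{k: tuple(v) if isinstance(v, list) else v
                        for k, v in d.items()})


def run_ensemble_track(ensemble: Ensemble, criteria: dict, outdir: Path) -> dict:
    """Interaction persistence over an ensemble; returns the summary dict."""
    summary: dict[str, Any] = {"n_models": ensemble.n_models}
    tables = {}
    if "hbond" in criteria:
        c = criteria["hbond"]
        crit = HBondCriterion(donor=_sel(c["donor"]), acceptor=_sel(c["acceptor"]),
                              dmax=float(c.get("dmax", 3.5)))
        res = persistence(ensemble, lambda m: hbond_satisfied(m, crit))
        summary["hbond"] = _persist_summary(res)
        tables["hbond"] = res
    if "stacking" in criteria:
        c = criteria["stacking"]
        ring1 = AromaticRing(tuple(int(i) for i in ensemble.select(_sel(c["ring1"]))))
        ring2 = AromaticRing(tuple(int(i) for i in ensemble.select(_sel(c["ring2"]))))
        lo, hi = c.get("angle_window", [60.0, 120.0])
        scrit = StackingCriterion(angle_min=lo, angle_max=hi,
                                  centroid_dmax=float(c.get("centroid_dmax", 5.5)))
        res = persistence(
            ensemble, lambda m: edge_to_face_satisfied(m, ring1, ring2, scrit))
        summary["stacking"] = _persist_summary(res)
        tables["stacking"] = res
    if "water_network" in criteria:
        c = criteria["water_network"]
        wspec = WaterNetworkSpec(anchors=_sel(c["anchors"]),
                                 expected_count=int(c.get("expected_count", 4)),
                                 link_dmax=float(c.get("link_dmax", 3.5)))
        res = persistence(ensemble, lambda m: _water_eval(m, wspec))
        summary["water_network"] = _persist_summary(res)
        tables["water_network"] = res
    for name, res in tables.items():
        rows = {"model_id": [m.model_id for m in ensemble.models],
                "satisfied": [int(b) for b in res.per_model]}
        if res.values:
            rows["value"] = res.values
        pd.DataFrame(rows).to_csv(outdir / f"persistence_{name}.tsv", sep="\t",
                                  index=False)
    return summary


def _water_eval(model, wspec):
    n, intact = water_network_state(model, wspec)
    return intact, float(n)


def _persist_summary(res) -> dict:
    return {"n_true": res.n_true, "n_models": res.n_models,
            "fraction": res.fraction, "percent": res.percent_rounded}


def run_trajectory_track(traj: Ensemble, net_params: dict, outdir: Path) -> dict:
    """RMSF, correlations, dynamical network and suboptimal paths."""
    ca = Selection(name="CA")
    prof = rmsf(traj, ca)
    pd.DataFrame({"chain": [c for c, _ in prof.resids],
                  "resid": [r for _, r in prof.resids],
                  "rmsf_A": prof.rmsf}).to_csv(outdir / "rmsf.tsv", sep="\t",
                                               index=False)
    corr = correlation_matrix(traj, ca)
    pd.DataFrame(corr.C, index=[r for _, r in corr.labels],
                 columns=[r for _, r in corr.labels]).to_csv(
        outdir / "correlation_matrix.csv")
    cmap = contact_fractions(traj, cutoff=float(net_params["cutoff"]),
                             mode=net_params.get("contact_mode", "heavy"))
    net = build_network(cmap, corr, fraction_threshold=float(net_params["fraction"]))
    edges = [(u[1], v[1], d["correlation"], d["weight"])
             for u, v, d in net.graph.edges(data=True)]
    pd.DataFrame(edges, columns=["resid_i", "resid_j", "correlation", "length"]
                 ).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    source = _find_node(net, net_params["source"])
    sink = _find_node(net, net_params["sink"])
    summary: dict[str, Any] = {
        "n_frames": traj.n_models,
        "mean_rmsf_A": float(prof.rmsf.mean()),
        "n_edges": net.graph.number_of_edges(),
    }
    ps = suboptimal_paths(net, source, sink, k=int(net_params["k"]))
    summary["source"], summary["sink"] = source[1], sink[1]
    summary["reachable"] = ps.reachable
    if ps.reachable:
        hist = path_histogram(ps, bins=20)
        pd.DataFrame({
            "rank": np.arange(1, len(ps.paths) + 1),
            "length": ps.lengths,
            "nodes": [" ".join(str(r) for _, r in p.nodes) for p in ps.paths],
        }).to_csv(outdir / "suboptimal_paths.tsv", sep="\t", index=False)
        summary.update(
            n_paths=len(ps.paths),
            optimal_length=float(ps.optimal.length),
            optimal_path=[int(r) for _, r in ps.optimal.nodes],
            mean_path_length=float(ps.lengths.mean()),
        )
        (outdir / "path_histogram.json").write_text(json.dumps({
            "bin_edges": hist.bin_edges.tolist(),
            "counts": hist.counts.tolist()}, indent=1))
    return summary


def _find_node(net, resid):
    matches = [n for n in net.graph.nodes if n[1] == int(resid)]
    if len(matches) != 1:
        raise ConfigError(f"residue {resid} matches {len(matches)} network nodes")
    return matches[0]


def run_assay_track(cfg_assay: dict, outdir: Path) -> dict:
    summary: dict[str, Any] = {}
    if cfg_assay.get("fp_csv"):
        ds = read_fp_csv(cfg_assay["fp_csv"],
                         probe_conc=float(cfg_assay.get("probe_conc_nM", 10.0)),
                         probe_kd=float(cfg_assay.get("probe_kd_nM", 10.0)))
        ki = fit_ki(ds)
        summary["ki"] = {
            "logKi": ki.logki, "Ki_M": ki.ki, "ci95_logKi": list(ki.ci95),
            "per_replicate_logKi": ki.per_replicate_logki,
        }
    if cfg_assay.get("dsf_csv"):
        curves = read_dsf_csv(cfg_assay["dsf_csv"])
        fits = [fit_boltzmann(c) for c in curves]
        tms = [f.tm for f in fits]
        summary["tm"] = {"Tm_C": tms, "mean_Tm_C": float(np.mean(tms))}
        if cfg_assay.get("dsf_reference_csv"):
            ref_fits = [fit_boltzmann(c)
                        for c in read_dsf_csv(cfg_assay["dsf_reference_csv"])]
            ref_mean = float(np.mean([f.tm for f in ref_fits]))
            summary["tm"]["delta_Tm_C"] = float(np.mean(tms) - ref_mean)
    if not summary:
        raise ConfigError("assay track: nothing to do")
    (outdir / "assay_results.json").write_text(json.dumps(summary, indent=1))
    return summary


def run_synth_track(seed: int, outdir: Path) -> dict:
    """Write one synthetic dataset of each kind under the output directory."""
    ens = make_interaction_ensemble(EnsembleSpec(seed=seed))
    write_multimodel_pdb(ens, outdir / "synthetic_ensemble.pdb")
    traj = make_correlated_trajectory(TrajectorySpec(n_frames=500, seed=seed))
    write_xyz_table(traj, outdir / "synthetic_trajectory.tsv")
    write_fp_csv(make_competition_dataset(CompetitionSpec(seed=seed)),
                 outdir / "synthetic_fp.csv")
    melt = make_melt_curve(MeltSpec(seed=seed))
    write_dsf_csv({"well1": melt}, outdir / "synthetic_dsf.csv")
    return {"files": sorted(p.name for p in outdir.iterdir())}


def run(config: RunConfig) -> dict:
    """Execute one track end-to-end and return the consolidated report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if config.track == "synth":
        body = run_synth_track(config.seed, outdir)
    elif config.track == "ensemble":
        body = run_ensemble_track(read_multimodel_pdb(config.input),
                                  config.criteria, outdir)
    elif config.track == "trajectory":
        reader = (read_xyz_table if str(config.input).endswith((".tsv", ".xyz"))
                  else read_multimodel_pdb)
        body = run_trajectory_track(reader(config.input), config.network, outdir)
    elif config.track == "assay":
        body = run_assay_track(config.assay, outdir)
    else:  # pragma: no cover - validate() guards this
        raise ConfigError(f"unknown track {config.track!r}")
    report = {
        "track": config.track,
        "results": body,
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                json.dumps(config.raw, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "elapsed_s": round(time.time() - t0, 3),
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    logger.info("track %s finished in %.2fs", config.track,
                report["provenance"]["elapsed_s"])
    return report
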