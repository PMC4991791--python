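"""End-to-end study orchestration.

One configuration drives the whole experiment: simulate recurrent
network instances, map spiking into functional / active / recruitment
networks, score small-world structure against density-matched nulls,
census directed triangle motifs across lag intervals, run the
triplet-timing analyses, and (optionally) the Poisson-surrogate control
and the imaging-inference arm on binned model activity.  A second
simulation arm with scaled synaptic weights shares structural seeds
with the first so the weight contrast is not confounded by topology
draws.
"""

from __future__ import annotations

import dataclasses
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dynamics as dyn
from .graph_stats import (GraphStatReport, MOTIFS, directed_clustering,
                          generate_null, mean_local_clustering,
                          small_world_scores)
from .graphs import WeightedDigraph
from .imaging import EventRaster, infer_functional_weights
from .mapping import (active_subnetwork, functional_network,
                      recruitment_network)
from .motif_timing import (CoincidenceStats, coincidence_analysis,
                           coincidence_rate_ratio, enumerate_pure_triplets)
from .network import SynapticNetwork, build_synaptic_network
from .params import (ConfigurationError, ConnectivityParams, NeuronParams,
                     SimulationConfig)
from .raster import SpikeRaster
from .simulate import excitatory_raster, run_session
from .synthetic import SurrogateSpec, poisson_rate_matched

REPORT_SCHEMA_VERSION = 1


@dataclass
class ExperimentConfig:
    n_naturalistic: int = 5
    n_double: int = 6
    weight_scale_double: float = 2.0
    T_list: tuple = (10.0, 25.0, 50.0)
    T_primary: float = 25.0
    n_null: int = 20
    base_seed: int = 1000
    n_coincidence_triplets: int = 20000
    run_surrogate: bool = True
    run_inference: bool = True
    inference_bin_ms: float = 50.0
    inference_max_cells: int = 200
    connectivity: ConnectivityParams = field(
        default_factory=ConnectivityParams)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.n_naturalistic < 1:
            raise ConfigurationError("need at least one simulation")
        if self.T_primary not in self.T_list:
            raise ConfigurationError("T_primary must be in T_list")


@dataclass
class SimulationReport:
    seed: int
    weight_scale: float
    dynamics: dyn.DynamicsSummary
    functional_stats: GraphStatReport
    recruitment_stats: GraphStatReport
    active_clustering_ratio: float
    recruitment_density: float
    census_by_T: dict                 # T -> {motif: binary census mean}
    binary_census: dict               # motif -> binary census at T_primary
    synaptic_census: dict             # motif -> binary census, synaptic
    coincidence: dict | None          # fan-in / convergence stats + ratio


def clustering_ratio_only(g: WeightedDigraph, n_null: int,
                          rng_seed: int, binary: bool = False) -> float:
    """Observed over mean-ER-null clustering, without path lengths."""
    C_obs = mean_local_clustering(g, binary=binary)
    rng = np.random.default_rng(rng_seed)
    C_null = [mean_local_clustering(generate_null(g, "erdos-renyi", rng),
                                    binary=binary)
              for _ in range(n_null)]
    return C_obs / float(np.mean(C_null))


def simulate_and_map(cfg: ExperimentConfig, seed: int,
                     weight_scale: float = 1.0):
    """Build a network, simulate, and derive the excitatory raster.

    Returns (net, raster, exc_raster).  ``weight_scale`` multiplies all
    synaptic weights after the draw, so two arms sharing ``seed`` have
    identical topology and proportional weights.
    """
    conn = dataclasses.replace(cfg.connectivity,
                               weight_scale=cfg.connectivity.weight_scale
                               * weight_scale)
    net = build_synaptic_network(conn, rng_seed=seed)
    sim_cfg = dataclasses.replace(cfg.simulation, seed=seed)
    raster, _ = run_session(net, cfg.neuron, sim_cfg)
    return net, raster, excitatory_raster(net, raster)


def analyze_simulation(cfg: ExperimentConfig, net: SynapticNetwork,
                       raster: SpikeRaster, exc: SpikeRaster, seed: int,
                       weight_scale: float = 1.0,
                       with_coincidence: bool = True) -> SimulationReport:
    """All per-simulation network and timing statistics."""
    func = functional_network(exc, T=cfg.T_primary)
    recruit = recruitment_network(func, net)
    active = active_subnetwork(net, exc)

    f_stats = small_world_scores(func, cfg.n_null, rng_seed=seed)
    r_stats = small_world_scores(recruit, cfg.n_null, rng_seed=seed + 1)
    a_ratio = clustering_ratio_only(active, cfg.n_null, rng_seed=seed + 2)

    census_by_T = {}
    for T in cfg.T_list:
        fT = func if T == cfg.T_primary else functional_network(exc, T=T)
        rT = recruit if T == cfg.T_primary else recruitment_network(fT, net)
        # Census on binary topologies: conditional-probability weights
        # scale with postsynaptic rate and would confound the motif
        # comparison, so only the recruited edge pattern is scored.
        c = directed_clustering(rT, binary=True)
        census_by_T[T] = {m: c.mean_coefficient(m) for m in MOTIFS}
    cb = directed_clustering(recruit, binary=True)
    binary_census = {m: cb.mean_coefficient(m) for m in MOTIFS}
    cs = directed_clustering(
        WeightedDigraph(net.excitatory_subgraph, kind="synaptic"),
        binary=True)
    synaptic_census = {m: cs.mean_coefficient(m) for m in MOTIFS}

    coincidence = None
    if with_coincidence:
        fi = enumerate_pure_triplets(net, "fan-in").subsample(
            cfg.n_coincidence_triplets, seed)
        cv = enumerate_pure_triplets(net, "convergence").subsample(
            cfg.n_coincidence_triplets, seed + 1)
        st_fi = coincidence_analysis(exc, fi)
        st_cv = coincidence_analysis(exc, cv)
        coincidence = {
            "fan_in": st_fi, "convergence": st_cv,
            "rate_ratio": coincidence_rate_ratio(st_fi, st_cv),
        }

    summary = dyn.summarize_dynamics(exc, cfg.simulation, net=net)
    return SimulationReport(
        seed=seed, weight_scale=weight_scale, dynamics=summary,
        functional_stats=f_stats, recruitment_stats=r_stats,
        active_clustering_ratio=a_ratio,
        recruitment_density=recruit.density,
        census_by_T=census_by_T, binary_census=binary_census,
        synaptic_census=synaptic_census, coincidence=coincidence)


def events_from_raster(raster: SpikeRaster, bin_ms: float = 50.0,
                       max_cells: int | None = None,
                       rng_seed: int = 0) -> EventRaster:
    """Bin model spiking into an imaging-style event raster.

    Trials are concatenated along the frame axis; a frame is an event
    when the neuron spiked in the bin.  Optionally restricts to a random
    subset of neurons (imaging fields sample a few hundred cells).
    """
    binned = raster.binned(bin_ms) > 0          # trials x neurons x bins
    E = binned.transpose(1, 0, 2).reshape(raster.n_neurons, -1)
    if max_cells is not None and raster.n_neurons > max_cells:
        sel = np.sort(np.random.default_rng(rng_seed).choice(
            raster.n_neurons, max_cells, replace=False))
        E = E[sel]
    return EventRaster(E, np.full(E.shape[0], np.inf),
                       np.ones(E.shape[0], dtype=bool),
                       frame_rate=1000.0 / bin_ms)


def inferred_clustering(events: EventRaster, rng_seed: int,
                        percentile: float = 95.0) -> dict:
    """Inference arm: undirected clustering and motif census at threshold.

    The motif census is computed on the binary topology of the map
    thresholded at ``percentile``; undirected clustering is the
    weighted (Onnela) coefficient of the full inferred weight matrix,
    since binary clustering of a percentile-thresholded map is pinned
    near its density and cannot express a collapse below it.
    """
    net = infer_functional_weights(events, rng_seed=rng_seed)
    g = net.threshold(percentile)
    census = directed_clustering(g, binary=True)
    return {
        "undirected_clustering": mean_local_clustering(net.graph(),
                                                       binary=False),
        "census": {m: census.mean_coefficient(m) for m in MOTIFS},
        "density": g.density,
    }


@dataclass
class StudyReport:
    config: ExperimentConfig
    naturalistic: list
    double_strength: list
    surrogate: dict | None
    inference: dict | None
    failures: list

    @property
    def partial(self) -> bool:
        return bool(self.failures)

    def headline(self) -> dict:
        """Aggregate mean +- std table of the printed statistics."""
        nat = self.naturalistic

        def agg(vals):
            return {"mean": float(np.mean(vals)), "std": float(np.std(vals)),
                    "n": len(vals)}

        out = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "functional_small_world": agg(
                [r.functional_stats.small_world_ratio for r in nat]),
            "recruitment_small_world": agg(
                [r.recruitment_stats.small_world_ratio for r in nat]),
            "recruitment_path_ratio": agg(
                [r.recruitment_stats.path_ratio for r in nat]),
            "recruitment_clustering_ratio": agg(
                [r.recruitment_stats.clustering_ratio for r in nat]),
            "active_clustering_ratio": agg(
                [r.active_clustering_ratio for r in nat]),
            "recruitment_density": agg(
                [r.recruitment_density for r in nat]),
            "excitatory_rate_hz": agg(
                [r.dynamics.firing_rate_mean for r in nat]),
            "branching_median": agg(
                [r.dynamics.branching_coeff_median for r in nat]),
        }
        if all(r.coincidence is not None for r in nat):
            out["coincidence_rate_ratio"] = agg(
                [r.coincidence["rate_ratio"] for r in nat])
            out["fan_in_mean_abs_dt_ms"] = agg(
                [r.coincidence["fan_in"].mean_abs_dt for r in nat])
            out["convergence_mean_abs_dt_ms"] = agg(
                [r.coincidence["convergence"].mean_abs_dt for r in nat])
        for T in self.config.T_list:
            for m in MOTIFS:
                out[f"recruitment_census_T{int(T)}_{m}"] = agg(
                    [r.census_by_T[T][m] for r in nat])
        if self.double_strength:
            for m in ("fan_in", "fan_out"):
                out[f"binary_census_{m}_naturalistic"] = agg(
                    [r.binary_census[m] for r in nat])
                out[f"binary_census_{m}_double"] = agg(
                    [r.binary_census[m] for r in self.double_strength])
        return out

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {"headline": self.headline(),
                   "partial": self.partial,
                   "failures": self.failures}
        if self.surrogate is not None:
            payload["surrogate"] = self.surrogate
        if self.inference is not None:
            payload["inference"] = self.inference
        with open(out / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        rows = []
        for arm, reports in (("naturalistic", self.naturalistic),
                             ("double", self.double_strength)):
            for r in reports:
                row = {"arm": arm, "seed": r.seed,
                       "functional_sw": r.functional_stats.small_world_ratio,
                       "recruitment_sw":
                       r.recruitment_stats.small_world_ratio,
                       "recruitment_density": r.recruitment_density,
                       "rate_hz": r.dynamics.firing_rate_mean}
                row.update({f"binary_{m}": r.binary_census[m]
                            for m in MOTIFS})
                rows.append(row)
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "simulations.csv", index=False)


def run_full_study(cfg: ExperimentConfig,
                   out_dir=None) -> StudyReport:
    """Run both arms plus controls; never raises on a stage failure.

    Failed stages are recorded as (stage, traceback) pairs and the
    report is marked partial.
    """
    failures = []
    naturalistic, double = [], []
    first_exc = None
    for k in range(cfg.n_naturalistic):
        seed = cfg.base_seed + k
        try:
            net, raster, exc = simulate_and_map(cfg, seed)
            if first_exc is None:
                first_exc = exc
            naturalistic.append(analyze_simulation(cfg, net, raster, exc,
                                                   seed))
        except Exception:
            failures.append((f"naturalistic[{k}]", traceback.format_exc()))
    for k in range(cfg.n_double):
        seed = cfg.base_seed + k          # shared structural seeds
        try:
            net, raster, exc = simulate_and_map(
                cfg, seed, weight_scale=cfg.weight_scale_double)
            double.append(analyze_simulation(
                cfg, net, raster, exc, seed,
                weight_scale=cfg.weight_scale_double,
                with_coincidence=False))
        except Exception:
            failures.append((f"double[{k}]", traceback.format_exc()))

    surrogate = inference = None
    if cfg.run_surrogate and first_exc is not None:
        try:
            surr = poisson_rate_matched(first_exc,
                                        SurrogateSpec(seed=cfg.base_seed))
            ev_real = events_from_raster(first_exc, cfg.inference_bin_ms,
                                         cfg.inference_max_cells,
                                         cfg.base_seed)
            ev_surr = events_from_raster(surr, cfg.inference_bin_ms,
                                         cfg.inference_max_cells,
                                         cfg.base_seed)
            surrogate = {
                "model": inferred_clustering(ev_real, cfg.base_seed),
                "poisson": inferred_clustering(ev_surr, cfg.base_seed),
            }
        except Exception:
            failures.append(("surrogate", traceback.format_exc()))
    if cfg.run_inference and first_exc is not None:
        try:
            ev = events_from_raster(first_exc, cfg.inference_bin_ms,
                                    cfg.inference_max_cells,
                                    cfg.base_seed + 7)
            inference = inferred_clustering(ev, cfg.base_seed + 7)
        except Exception:
            failures.append(("inference", traceback.format_exc()))

    report = StudyReport(cfg, naturalistic, double, surrogate, inference,
                         failures)
    if out_dir is not None:
        report.save(out_dir)
    return report
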