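"""End-to-end orchestration: spikes -> networks -> triads -> PID -> statistics.

The pipeline stages mirror the analysis flow: bin spike trains at each
timescale, build the jitter-significant TE network, enumerate and classify
synergistic triads, decompose each triad's multivariate TE, then aggregate
and run the motif-level statistics.  Every stage's tabular output is written
as TSV next to a JSON manifest recording the configuration, the seed split
and content hashes, so a run is reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .infoflow import EffectiveNetwork, build_network
from .motifs import enumerate_triads, triads_to_dataframe
from .pid import normalize_pid, pid_decompose
from .raster import (
    CANONICAL_TIMESCALES,
    SpikeTrain,
    TimescaleSpec,
    bin_spikes,
    read_spike_file,
    write_spike_file,
)
from .spikesim import GroundTruthGraph, SimConfig, generate_ground_truth, simulate, write_ground_truth

__all__ = ["RunConfig", "run_pipeline", "triad_pid_table", "make_fixtures"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (flat, YAML-serializable)."""

    # input: either a spike file or a simulation block
    input_path: str | None = None
    simulate: dict | None = None
    timescales: Sequence[dict] | None = None  # label/bin_width_ms/delay_bins
    alpha: float = 0.001
    n_jitter: int = 5000
    jitter_window_ms: float = 10.0
    pid_method: str = "imin"
    seed: int = 0
    out_dir: str = "synflow_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def specs(self) -> list[TimescaleSpec]:
        if self.timescales is None:
            return list(CANONICAL_TIMESCALES)
        return [
            TimescaleSpec(
                t.get("label", f"TS{i + 1}"),
                float(t["bin_width_ms"]),
                int(t["delay_bins"]),
            )
            for i, t in enumerate(self.timescales)
        ]


def triad_pid_table(
    trains: Sequence[SpikeTrain],
    net: EffectiveNetwork,
    method: str = "imin",
    network_id: int | str = 0,
) -> pd.DataFrame:
    """One row per synergistic triad with motif class, PID terms and weights.

    Synergy, redundancy and mvTE are reported raw (bits) and normalized by
    the receiver entropy (NaN where that entropy is zero; such rows are
    excluded from normalized aggregates downstream).
    """
    triads = enumerate_triads(net)
    base = triads_to_dataframe(triads, network_id)
    if base.empty:
        return base
    spec = net.spec
    series = {t.neuron_id: bin_spikes(t, spec) for t in trains}
    extra = []
    for t in triads:
        res = pid_decompose(
            series[t.sender_a], series[t.sender_b], series[t.receiver],
            spec, method=method,
        )
        norm = normalize_pid(res, "receiver_entropy")
        extra.append(
            {
                "te_a": res.te_a,
                "te_b": res.te_b,
                "mvte": res.mvte,
                "redundancy": res.redundancy,
                "synergy": res.synergy,
                "unique_a": res.unique_a,
                "unique_b": res.unique_b,
                "synergy_norm": norm["synergy"],
                "redundancy_norm": norm["redundancy"],
                "mvte_norm": norm["mvte"],
                "receiver_entropy": res.receiver_entropy,
                "sender_entropy": 0.5 * (res.sender_entropy_a + res.sender_entropy_b),
                "mi_senders_norm": res.mi_senders_norm,
                "pid_method": res.method,
            }
        )
    return pd.concat([base, pd.DataFrame(extra)], axis=1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulate_from_block(block: dict, seed: int) -> tuple[list[SpikeTrain], GroundTruthGraph]:
    planted = [
        (int(p[0]), int(p[1]), p[2] if len(p) > 2 else None)
        for p in block.get("planted", [])
    ]
    graph = generate_ground_truth(
        int(block.get("n_neurons", 12)),
        float(block.get("background_density", 0.0)),
        planted,
        tuple(block.get("weight_range", (0.4, 0.7))),
        seed=seed,
    )
    cfg = SimConfig(
        duration_ms=float(block.get("duration_ms", 600_000.0)),
        baseline_rate_lognormal=tuple(block.get("baseline_rate_lognormal", (0.242, 1.0))),
        burst_gain=float(block.get("burst_gain", 2.5)),
        coupling_delay_ms=float(block.get("coupling_delay_ms", 1.0)),
        seed=seed + 1,
    )
    return simulate(graph, cfg), graph


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Stage order: load/simulate -> effective networks (one per timescale) ->
    triad classification + PID -> motif summary + statistics.  A stage
    failure aborts with the stage name; outputs of completed stages remain
    on disk.  Re-running with the same config and seed reproduces all
    numeric outputs exactly.
    """
    from .motifstats import (  # deferred: keeps import graph acyclic
        recurrent_vs_feedback_test,
        rm_anova,
        summarize,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": [],
        "artifacts": {},
    }
    ss = np.random.SeedSequence(config.seed)
    seed_sim, seed_net = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            manifest["stages"].append(
                {"stage": name, "seconds": round(time.perf_counter() - t0, 3)}
            )
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return deco

    @stage("input")
    def trains() -> list[SpikeTrain]:
        if config.input_path is not None:
            path = Path(config.input_path)
            if not path.exists():
                raise FileNotFoundError(f"input spike file {path} does not exist")
            return read_spike_file(path)
        if config.simulate is None:
            raise ValueError("config needs either input_path or a simulate block")
        tr, graph = _simulate_from_block(config.simulate, seed_sim)
        write_spike_file(tr, out / "spikes.txt")
        write_ground_truth(graph, out / "ground_truth.txt")
        manifest["artifacts"]["spikes"] = "spikes.txt"
        manifest["artifacts"]["ground_truth"] = "ground_truth.txt"
        return tr

    specs = config.specs()
    all_triads = []
    networks = []

    @stage("networks")
    def _networks():
        for i, spec in enumerate(specs):
            net = build_network(
                trains,
                spec,
                n_jitter=config.n_jitter,
                alpha=config.alpha,
                jitter_window_ms=config.jitter_window_ms,
                seed=seed_net + i,
            )
            networks.append(net)
            fname = f"network_{spec.label}.tsv"
            net.write_edge_list(out / fname)
            manifest["artifacts"][f"network_{spec.label}"] = fname

    @stage("triads")
    def _triads():
        for net in networks:
            df = triad_pid_table(trains, net, config.pid_method, net.spec.label)
            if not df.empty:
                all_triads.append(df)

    triad_df = (
        pd.concat(all_triads, ignore_index=True) if all_triads else pd.DataFrame()
    )

    @stage("stats")
    def _stats():
        triad_df.to_csv(out / "triads.tsv", sep="\t", index=False)
        manifest["artifacts"]["triads"] = "triads.tsv"
        results = []
        if not triad_df.empty:
            summary = summarize(triad_df)
            summary.to_csv(out / "motif_summary.tsv", sep="\t", index=False)
            manifest["artifacts"]["motif_summary"] = "motif_summary.tsv"
            try:
                results.append(recurrent_vs_feedback_test(summary).as_row())
            except ValueError as exc:
                logger.info("recurrent_vs_feedback skipped: %s", exc)
            try:
                results.extend(r.as_row() for r in rm_anova(summary))
            except ValueError as exc:
                logger.info("rm_anova skipped: %s", exc)
        pd.DataFrame(results).to_csv(out / "stats.tsv", sep="\t", index=False)
        manifest["artifacts"]["stats"] = "stats.tsv"

    manifest["hashes"] = {
        name: _sha256(out / fname) for name, fname in manifest["artifacts"].items()
    }
    manifest["seeds"] = {"simulate": seed_sim, "networks": seed_net}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def make_fixtures(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Write small reference inputs: logic-gate series, a planted network,
    or independent null trains."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: list[Path] = []
    if kind == "gates":
        n = 4096
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        k_dup = a.copy()
        df = pd.DataFrame(
            {
                "src_a": a,
                "src_b": b,
                "xor_target": a ^ b,
                "and_target": a & b,
                "unq_target": a,
                "dup_src_b": k_dup,
            }
        )
        path = out / "gates.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    elif kind == "planted_network":
        graph = generate_ground_truth(
            9, 0.0, [(2, 0, None), (0, 2, None), (1, 1, "parallel")], seed=seed
        )
        cfg = SimConfig(duration_ms=300_000.0, seed=seed + 1)
        trains = simulate(graph, cfg)
        spike_path = out / "planted_spikes.txt"
        gt_path = out / "planted_ground_truth.txt"
        write_spike_file(trains, spike_path)
        write_ground_truth(graph, gt_path)
        written += [spike_path, gt_path]
    elif kind == "null_network":
        graph = generate_ground_truth(10, 0.0, seed=seed)
        cfg = SimConfig(duration_ms=300_000.0, burst_gain=1.0, seed=seed + 1)
        trains = simulate(graph, cfg)
        path = out / "null_spikes.txt"
        write_spike_file(trains, path)
        written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
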