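"""Cross-evidence congruence and the end-to-end delimitation pipeline.

Integrative taxonomy treats a split as corroborated when independent
evidence streams — molecular clusters, GMYC entities, morphometric
clusters, mating compatibility, host association — delimit the same
groups. This module reduces each stream to a :class:`Partition` over the
same specimens, quantifies pairwise agreement with the adjusted Rand
index, forms the strict consensus (specimens stay together only when every
stream keeps them together), and orchestrates the whole pipeline:
distances -> NJ -> NPRS -> GMYC, diagnostics, morphometrics, mating
components, congruence report.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .distances import (
    DistanceMatrix,
    LabeledAlignment,
    at_content,
    distance_matrix,
    five_number_summary,
    group_divergence_summary,
)
from .diagnostics import diagnostic_site_fraction, find_diagnostics, site_classes
from .gmyc import gmyc_fit
from .morpho import anova_by_axis, average_replicates, cluster_specimens, gpa, relative_warps
from .partition import Partition
from .simulate import MatingMatrix, SimConfig, simulate_dataset
from .trees import collapse_haplotypes, neighbor_joining, nprs_smooth

__all__ = [
    "MatingMatrix",
    "Partition",
    "mating_components",
    "partition_agreement",
    "consensus_delimitation",
    "molecular_clusters",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def mating_components(m: MatingMatrix) -> Partition:
    """Connected components of the mating-compatibility graph.

    Populations are joined whenever courtship/mating was observed in either
    reciprocal direction of their cross; components are the blocks.
    """
    k = len(m.groups)
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if m.observed[i, j] or m.observed[j, i]:
                parent[find(i)] = find(j)
    roots = {}
    assignment = {}
    for i, g in enumerate(m.groups):
        r = find(i)
        assignment[g] = roots.setdefault(r, len(roots))
    return Partition(assignment, provenance="mating")


def partition_agreement(a: Partition, b: Partition) -> float:
    """Adjusted Rand index between two partitions of the same elements."""
    return a.ari(b)


def consensus_delimitation(
    partitions: list[Partition],
) -> tuple[Partition, pd.DataFrame]:
    """Strict consensus of evidence streams plus a congruence table.

    Two elements share a consensus block iff they are co-clustered in ALL
    streams, so the consensus can only split blocks, never merge them. The
    congruence table holds the pairwise ARI matrix and per-stream block
    counts (streams named by provenance, deduplicated with suffixes).
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 evidence streams")
    elements = set(partitions[0].assignment)
    for p in partitions[1:]:
        if set(p.assignment) != elements:
            raise ValueError("all partitions must cover the same elements")
    keys: dict = {}
    assignment = {}
    for el in sorted(elements, key=str):
        key = tuple(p.assignment[el] for p in partitions)
        assignment[el] = keys.setdefault(key, len(keys))
    consensus = Partition(assignment, provenance="consensus")

    names = []
    for p in partitions:
        base = p.provenance or "stream"
        name = base
        k = 2
        while name in names:
            name = f"{base}{k}"
            k += 1
        names.append(name)
    ari = np.eye(len(partitions))
    for i in range(len(partitions)):
        for j in range(i + 1, len(partitions)):
            ari[i, j] = ari[j, i] = partitions[i].ari(partitions[j])
    table = pd.DataFrame(ari, index=names, columns=names)
    table["n_blocks"] = [p.n_blocks for p in partitions]
    return consensus, table


def molecular_clusters(dm: DistanceMatrix, k: int) -> Partition:
    """Average-linkage clustering of the K2P matrix cut at ``k`` clusters."""
    cond = squareform(dm.values, checks=False)
    z = linkage(cond, method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    return Partition(dict(zip(dm.ids, (int(l) for l in labels))), provenance="molecular")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "simulate": True,
    "seed": 0,
    "n_species": 3,
    "n_per_species": 10,
    "k": None,  # clusters for molecular/morpho cutting; defaults to n_species
    "axes": 10,
    "df": 3,
    "collapse_haplotypes": True,
    "outgroup": None,
    "root_age": 1.0,
    "paths": {},
}


def _load_config(config) -> dict:
    cfg = dict(_DEFAULT_CONFIG)
    if config is None:
        return cfg
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            loaded = yaml.safe_load(fh) or {}
    else:
        loaded = dict(config)
    cfg.update(loaded)
    return cfg


def run_pipeline(config=None, outdir=None) -> dict:
    """Execute the full integrative delimitation on one dataset.

    ``config`` is a dict, or a YAML/JSON path, with the keys of
    ``_DEFAULT_CONFIG`` (all optional). With ``simulate: true`` a synthetic
    dataset is generated from ``seed``; otherwise ``paths`` must point to
    an alignment (FASTA), metadata (TSV with id/group columns), and
    optionally landmarks (TPS) and a mating matrix (TSV). Every analysis
    stage records an ok/skipped/failed status; one failed stage does not
    abort the others. Returns the report dict (also written as JSON/TSV
    under ``outdir`` when given).
    """
    cfg = _load_config(config)
    t0 = time.time()
    report: dict = {"config": {k: v for k, v in cfg.items() if k != "paths"},
                    "stages": {}, "results": {}}
    res = report["results"]
    stages = report["stages"]

    # ---- inputs -----------------------------------------------------------
    landmarks = mating = None
    truth: Partition | None = None
    if cfg["simulate"]:
        sim = SimConfig(
            n_species=int(cfg["n_species"]),
            n_per_species=int(cfg["n_per_species"]),
            seed=int(cfg["seed"]),
        )
        data = simulate_dataset(sim)
        aln, landmarks, mating, truth = data.alignment, data.landmarks, data.mating, data.partition
        membership = dict(truth.assignment)
        if outdir is not None:
            data.write(Path(outdir) / "inputs")
    else:
        paths = cfg["paths"]
        meta = pd.read_csv(paths["metadata"], sep="\t")
        membership = dict(zip(meta["id"].astype(str), meta["group"].astype(str)))
        aln = LabeledAlignment.from_fasta(paths["alignment"], labels=membership)
        if paths.get("landmarks"):
            from .morpho import read_tps

            landmarks = read_tps(paths["landmarks"])
            landmarks.groups = membership
        if paths.get("mating"):
            mt = pd.read_csv(paths["mating"], sep="\t", index_col=0)
            mating = MatingMatrix(
                list(mt.index), (mt.values == "+"), np.full(mt.shape, 10, dtype=int)
            )
    k = int(cfg["k"]) if cfg.get("k") else len(set(membership.values()))

    streams: list[Partition] = []

    # ---- molecular distances ---------------------------------------------
    try:
        dm = distance_matrix(aln)
        summary = group_divergence_summary(dm, aln.labels)
        res["at_content_pct"] = round(100.0 * at_content(aln), 1)
        res["divergence_summary"] = summary.to_dict(orient="records")
        within = summary[(summary["scope"] == "overall") & (summary["class"] == "within")]
        between = summary[(summary["scope"] == "overall") & (summary["class"] == "between")]
        res["within_mean_pct"] = round(100.0 * float(within["mean"].iloc[0]), 2)
        res["between_mean_pct"] = round(100.0 * float(between["mean"].iloc[0]), 2)
        focal = [
            dm.values[i, j]
            for i in range(len(dm.ids))
            for j in range(i + 1, len(dm.ids))
            if aln.labels[i] != aln.labels[j]
        ]
        res["between_distance_boxplot"] = five_number_summary(focal)
        streams.append(molecular_clusters(dm, k))
        stages["distances"] = "ok"
    except Exception as exc:  # pragma: no cover - degradation path
        stages["distances"] = f"failed: {exc}"
        dm = None

    # ---- NJ -> NPRS -> GMYC ----------------------------------------------
    try:
        if dm is None:
            raise RuntimeError("no distance matrix")
        gm_aln, members = (aln, {i: [i] for i in aln.ids})
        if cfg["collapse_haplotypes"]:
            gm_aln, members = collapse_haplotypes(aln)
        res["n_haplotypes"] = len(gm_aln)
        gm_dm = distance_matrix(gm_aln) if cfg["collapse_haplotypes"] else dm
        nj = neighbor_joining(gm_dm, outgroup=cfg.get("outgroup"))
        if cfg.get("outgroup"):
            from .trees import drop_taxon

            nj = drop_taxon(nj, cfg["outgroup"])
        chrono = nprs_smooth(nj, root_age=float(cfg["root_age"]))
        fit = gmyc_fit(chrono, df=int(cfg["df"]))
        expanded = {
            spec: block
            for rep, block in fit.entities.assignment.items()
            for spec in members[rep]
        }
        gmyc_part = Partition(expanded, provenance="gmyc")
        streams.append(gmyc_part)
        res["gmyc"] = {
            "threshold": fit.threshold,
            "lnl_gmyc": fit.lnl_gmyc,
            "lnl_null": fit.lnl_null,
            "lr": fit.lr,
            "p_value": fit.p_value,
            "n_entities": fit.n_entities,
            "n_clusters": fit.n_clusters,
            "n_singletons": fit.n_singletons,
            "entities": {t: int(b) for t, b in sorted(expanded.items())},
        }
        stages["gmyc"] = "ok"
    except Exception as exc:
        stages["gmyc"] = f"failed: {exc}"

    # ---- diagnostics ------------------------------------------------------
    try:
        table = find_diagnostics(aln)
        sites = site_classes(table)
        res["diagnostics"] = {
            "n_characters": int(len(table)),
            "n_pure_characters": int((table["klass"] == "pure").sum()),
            "n_private_characters": int((table["klass"] == "private").sum()),
            "n_sites": int(len(sites)),
            "n_pure_sites": int((sites["klass"] == "pure").sum()),
            "n_private_sites": int((sites["klass"] == "private").sum()),
            "site_fraction_pct": diagnostic_site_fraction(table, aln.length),
        }
        if outdir is not None:
            table.to_csv(Path(outdir) / "diagnostics.tsv", sep="\t", index=False)
        stages["diagnostics"] = "ok"
    except Exception as exc:
        stages["diagnostics"] = f"failed: {exc}"

    # ---- morphometrics ----------------------------------------------------
    try:
        if landmarks is None:
            stages["morpho"] = "skipped: no landmark input"
        else:
            averaged = average_replicates(landmarks)
            aligned, consensus = gpa(averaged)
            warps = relative_warps(aligned, specimen_ids=averaged.specimen_ids,
                                   consensus=consensus)
            labels = [membership[s] for s in averaged.specimen_ids]
            anova = anova_by_axis(warps, labels, axes=3)
            part = cluster_specimens(warps, k=k, n_axes=int(cfg["axes"]))
            streams.append(part)
            res["morpho"] = {
                "variance_pct": [round(100.0 * v, 2) for v in warps.variance_fractions[:4]],
                "anova": anova.to_dict(orient="records"),
                "n_clusters": part.n_blocks,
            }
            stages["morpho"] = "ok"
    except Exception as exc:
        stages["morpho"] = f"failed: {exc}"

    # ---- mating -----------------------------------------------------------
    try:
        if mating is None:
            stages["mating"] = "skipped: no mating input"
        else:
            pop_part = mating_components(mating)
            streams.append(pop_part.lift(membership, provenance="mating"))
            res["mating"] = {
                "matrix": mating.to_dataframe().to_dict(orient="index"),
                "n_components": pop_part.n_blocks,
            }
            stages["mating"] = "ok"
    except Exception as exc:
        stages["mating"] = f"failed: {exc}"

    # ---- host association (flagged non-independent of sampling design) ----
    host_part = Partition(dict(membership), provenance="host")
    streams.append(host_part)

    # ---- consensus --------------------------------------------------------
    try:
        usable = [p for p in streams if set(p.assignment) == set(membership)]
        consensus_part, congruence = consensus_delimitation(usable)
        res["consensus"] = {
            "n_blocks": consensus_part.n_blocks,
            "blocks": {str(b): sorted(map(str, els)) for b, els in consensus_part.blocks().items()},
            "congruence_ari": congruence.drop(columns="n_blocks").round(6).to_dict(),
            "stream_block_counts": congruence["n_blocks"].to_dict(),
        }
        if truth is not None:
            res["consensus"]["ari_vs_truth"] = consensus_part.ari(truth)
        stages["consensus"] = "ok"
    except Exception as exc:
        stages["consensus"] = f"failed: {exc}"

    logger.info("pipeline finished in %.2f s", time.time() - t0)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        # timings stay in the log so the JSON is byte-identical across reruns
        with open(out / "report.json", "w") as fh:
            json.dump(_stable(report), fh, indent=2, sort_keys=True)
        logger.info("pipeline report written to %s", out / "report.json")
    return report


def _stable(obj):
    """JSON-serializable deep copy with deterministic float formatting."""
    if isinstance(obj, dict):
        return {str(k): _stable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return 0.0 if v == 0 else round(v, 12)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_stable(v) for v in obj.tolist()]
    return obj
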