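"""Pipeline driver: per-trajectory analysis bundles and apo/holo comparison.

``run_analyze`` executes every stage (RMSD series, RMSF, Rgyr, inter-domain
distances, domain-center clouds, membrane contacts and burial, secondary
structure, clustering, network communities) on one trajectory and writes a
bundle directory of TSV series plus one ``summary.json``. ``run_compare``
assembles two bundles into the apo/holo comparison: the per-domain
inter/intra decomposition of Cα-RMSD contrasts, state comparisons of
distances and radii, the sampling switch report, and count deltas.
All outputs are deterministic given inputs and configuration; provenance
(config hash, package version) is embedded in every summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import geometry, sampling
from .conformation import (cluster_trajectory, correlation_matrix, build_network,
                           detect_communities, sse_fractions)
from .errors import ConfigError, SelectionError
from .model import (DomainMap, Trajectory, load_domain_map, read_multimodel_pdb,
                    select_atoms, select_membrane)

logger = logging.getLogger("cardyn")

RECEPTOR_DOMAINS = ("AB", "HI", "TM", "CS", "SI")


@dataclass
class AnalysisConfig:
    """Everything one analysis run depends on."""

    trajectory: str
    domain_map: str
    out_dir: str
    fit_domain: str = "TM"
    equilibration_cut: int = 0
    contact_cutoff: float = 2.5  # Å
    cluster_cutoff: float = 2.5  # Å RMSD
    network_contact_cutoff: float = 4.5  # Å
    network_occupancy: float = 0.75
    do_sse: bool = True
    do_cluster: bool = True
    do_network: bool = True
    sse_stride: int = 10
    report_precision: int = 1

    def __post_init__(self):
        for name in ("contact_cutoff", "cluster_cutoff", "network_contact_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.network_occupancy <= 1:
            raise ConfigError("network_occupancy must be in (0, 1]")
        if self.equilibration_cut < 0:
            raise ConfigError("equilibration_cut must be >= 0")

    def config_hash(self) -> str:
        # the hash covers analysis parameters, not where the bundle lands
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ComparisonReport:
    """Apo/holo comparison assembled from two analysis bundles."""

    decomposition: list[geometry.DecompositionResult]
    state_comparisons: list[geometry.StateComparison]
    switch: sampling.SwitchReport | None
    contact_means: dict[str, dict[str, float]]  # group -> {apo, holo}
    sse_deltas: dict[str, dict[str, float]]  # domain -> label -> holo-apo
    cluster_counts: dict[str, int]
    community_counts: dict[str, int]


def _write_series_tsv(path: Path, series: geometry.MetricSeries) -> None:
    with open(path, "w") as fh:
        fh.write("frame\tvalue\n")
        for i, v in enumerate(series.per_frame_values):
            fh.write(f"{i}\t{v:.6f}\n")


def _series_summary(series: geometry.MetricSeries, cut: int) -> dict:
    vals = series.per_frame_values[cut:]
    return {
        "name": series.name, "units": series.units,
        "fit": series.fit_selection, "measure": series.measure_selection,
        "mean": float(np.mean(vals)), "sd": float(np.std(vals)),
        "n_frames": int(len(series)), "cut": int(cut),
    }


def _summary_dict(s: sampling.SamplingSummary) -> dict:
    return {
        "centroid": [float(v) for v in s.centroid],
        "covariance_trace": s.covariance_trace,
        "principal_extents": [float(v) for v in s.principal_extents],
        "planar_spread": s.planar_spread,
        "normal_spread": s.normal_spread,
        "hull_volume": s.hull_volume,
    }


def run_analyze(config: AnalysisConfig, traj: Trajectory | None = None,
                dmap: DomainMap | None = None) -> dict:
    """Run every enabled stage on one trajectory; write the bundle; return the summary."""
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dmap is None:
        dmap = load_domain_map(config.domain_map)
    if traj is None:
        traj = read_multimodel_pdb(config.trajectory)
    cut = config.equilibration_cut
    if cut >= traj.n_frames:
        raise ConfigError(
            f"equilibration cut {cut} >= {traj.n_frames} frames in {config.trajectory}")
    fit_sel = select_atoms(traj, dmap, config.fit_domain, atom_name="CA")
    receptor_domains = [d for d in RECEPTOR_DOMAINS if d in dmap.domains]
    receptor_ranges = [r for d in receptor_domains for r in dmap.domains[d]]
    receptor_sel = select_atoms(traj, dmap, receptor_ranges, atom_name="CA")

    summary: dict = {
        "domains": receptor_domains,
        "fit_domain": config.fit_domain,
        "series": {},
        "rmsf": {},
        "clouds": {},
        "contacts": {},
        "provenance": {
            "config": {k: v for k, v in asdict(config).items() if k != "out_dir"},
            "config_hash": config.config_hash(),
            "n_frames": traj.n_frames,
        },
    }

    def stage(name):
        logger.info("=== stage %s (t=%.1fs) ===", name, time.monotonic() - t0)

    # --- RMSD series: receptor + per-domain fit-to-TM and fit-to-self ------
    stage("rmsd")
    series_out: dict[str, geometry.MetricSeries] = {}
    series_out["rmsd_receptor"] = geometry.rmsd_series(
        traj, None, fit_sel, receptor_sel, name="rmsd_receptor")
    for dom in receptor_domains:
        dsel = select_atoms(traj, dmap, dom, atom_name="CA")
        series_out[f"rmsd_overall_{dom}"] = geometry.rmsd_series(
            traj, None, fit_sel, dsel, name=f"rmsd_overall_{dom}")
        if len(dsel) >= 3:
            intra = geometry.rmsd_series(traj, None, dsel, dsel,
                                         name=f"rmsd_intra_{dom}")
        else:
            # a domain of one or two particles has no internal deformation
            intra = geometry.MetricSeries(
                name=f"rmsd_intra_{dom}",
                per_frame_values=np.zeros(traj.n_frames), units="Å",
                fit_selection=dsel.label, measure_selection=dsel.label)
        series_out[f"rmsd_intra_{dom}"] = intra

    # --- distances, end-to-end, Rgyr ---------------------------------------
    stage("distances")
    for a, b in (("AB", config.fit_domain), ("SI", config.fit_domain)):
        sel_a = select_atoms(traj, dmap, a, atom_name="CA")
        sel_b = select_atoms(traj, dmap, b, atom_name="CA")
        series_out[f"dist_{a}_{b}"] = geometry.center_distance_series(
            traj, sel_a, sel_b, fit_sel, name=f"dist_{a}_{b}")
    series_out["end_to_end"] = geometry.end_to_end_series(traj, fit_sel)
    series_out["rgyr_receptor"] = geometry.rgyr_series(
        traj, receptor_sel, name="rgyr_receptor")
    # by terminus: extracellular (N-terminal) AB+HI, intracellular (C-terminal) CS+SI
    for label, doms in (("nterm", ("AB", "HI")), ("cterm", ("CS", "SI"))):
        ranges = [r for d in doms if d in dmap.domains for r in dmap.domains[d]]
        sel = select_atoms(traj, dmap, ranges, atom_name="CA")
        series_out[f"rgyr_{label}"] = geometry.rgyr_series(
            traj, sel, name=f"rgyr_{label}")

    for key, series in series_out.items():
        _write_series_tsv(out / f"{key}.tsv", series)
        summary["series"][key] = _series_summary(series, cut)

    # --- RMSF ---------------------------------------------------------------
    stage("rmsf")
    if traj.n_frames >= 2:
        profile = geometry.rmsf_profile(traj, fit_sel, receptor_sel)
        with open(out / "rmsf.tsv", "w") as fh:
            fh.write("residue_id\trmsf\n")
            for rid, v in zip(profile.residue_ids, profile.values):
                fh.write(f"{rid}\t{v:.6f}\n")
        for dom in receptor_domains:
            ranges = dmap.resolve(dom)
            mask = np.array([any(lo <= r <= hi for _, lo, hi in ranges)
                             for r in profile.residue_ids])
            summary["rmsf"][dom] = float(np.mean(profile.values[mask]))

    # --- domain-center clouds ----------------------------------------------
    stage("clouds")
    for dom in ("AB", "CS", "SI"):
        if dom not in dmap.domains:
            continue
        dsel = select_atoms(traj, dmap, dom, atom_name="CA")
        cloud = sampling.center_cloud(traj, dsel, fit_sel, equilibration_cut=cut)
        with open(out / f"cloud_{dom}.tsv", "w") as fh:
            fh.write("frame\tx\ty\tz\n")
            for i, p in enumerate(cloud.points):
                fh.write(f"{i + cut}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\n")
        summary["clouds"][dom] = _summary_dict(sampling.sampling_summary(cloud))

    # --- membrane contacts & burial ------------------------------------------
    stage("contacts")
    try:
        mem_sel = select_membrane(traj, dmap)
    except SelectionError:
        mem_sel = None
        logger.info("no membrane atoms; contact/burial stages skipped")
    if mem_sel is not None:
        for group in sorted(dmap.groups):
            gsel = select_atoms(traj, dmap, group)
            contacts = sampling.contact_count_series(
                traj, gsel, mem_sel, cutoff=config.contact_cutoff, group_name=group)
            with open(out / f"contacts_{group}.tsv", "w") as fh:
                fh.write("frame\tcount\n")
                for i, c in enumerate(contacts.per_frame_counts):
                    fh.write(f"{i}\t{c}\n")
            mean = float(np.mean(contacts.per_frame_counts[cut:]))
            summary["contacts"][group] = {
                "mean": mean, "mean_rounded": int(round(mean)),
                "cutoff": config.contact_cutoff,
            }
        tyr_group = "ITAM_TYR" if "ITAM_TYR" in dmap.groups else None
        if tyr_group:
            tsel = select_atoms(traj, dmap, tyr_group)
            burial = sampling.burial_depth_series(
                traj, tsel, dmap.membrane_slab_halfwidth, fit_sel=fit_sel)
            _write_series_tsv(out / "burial_ITAM_TYR.tsv", burial)
            vals = burial.per_frame_values[cut:]
            summary["burial_ITAM_TYR"] = {
                "mean": float(np.mean(vals)), "max": float(np.max(vals)),
                "buried_fraction": float(np.mean(vals > 0)),
            }

    # --- secondary structure -------------------------------------------------
    if config.do_sse:
        stage("sse")
        summary["sse"] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for dom in receptor_domains:
                summary["sse"][dom] = sse_fractions(
                    traj, dmap, dom, stride=config.sse_stride)
        with open(out / "sse_fractions.tsv", "w") as fh:
            fh.write("domain\tH\tE\tC\n")
            for dom, fr in summary["sse"].items():
                fh.write(f"{dom}\t{fr['H']:.4f}\t{fr['E']:.4f}\t{fr['C']:.4f}\n")

    # --- clustering ------------------------------------------------------------
    if config.do_cluster:
        stage("cluster")
        assignment = cluster_trajectory(traj, receptor_sel,
                                        cutoff=config.cluster_cutoff)
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("frame\tcluster\n")
            for i, lab in enumerate(assignment.labels):
                fh.write(f"{i}\t{lab}\n")
        summary["clusters"] = {
            "n_clusters": assignment.n_clusters,
            "cutoff": config.cluster_cutoff,
            "representatives": list(assignment.representatives),
        }

    # --- correlation network ----------------------------------------------------
    if config.do_network:
        stage("network")
        corr = correlation_matrix(traj, receptor_sel, fit_sel)
        graph = build_network(traj, corr, receptor_sel,
                              contact_cutoff=config.network_contact_cutoff,
                              occupancy=config.network_occupancy)
        with open(out / "network_edges.tsv", "w") as fh:
            fh.write("i\tj\tweight\toccupancy\n")
            for i, j, data in sorted(graph.edges(data=True)):
                fh.write(f"{i}\t{j}\t{data['weight']:.6f}\t{data['occupancy']:.4f}\n")
        partition = detect_communities(graph, dmap, corr.node_residue_ids)
        summary["communities"] = {
            "n_communities": partition.n_communities,
            "modularity": partition.modularity,
            "per_domain": partition.per_domain_counts,
        }
        with open(out / "communities.json", "w") as fh:
            json.dump({str(k): v for k, v in partition.node_community.items()},
                      fh, sort_keys=True, indent=1)

    stage("done")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
    return summary


def _load_summary(bundle_dir: str | Path) -> dict:
    path = Path(bundle_dir) / "summary.json"
    if not path.exists():
        raise ConfigError(f"not an analysis bundle (no summary.json): {bundle_dir}")
    return json.loads(path.read_text())


def _summary_from_dict(d: dict) -> sampling.SamplingSummary:
    return sampling.SamplingSummary(
        centroid=np.asarray(d["centroid"]),
        covariance_trace=d["covariance_trace"],
        principal_extents=np.asarray(d["principal_extents"]),
        planar_spread=d["planar_spread"],
        normal_spread=d["normal_spread"],
        hull_volume=d["hull_volume"],
    )


def run_compare(apo_bundle: str | Path, holo_bundle: str | Path,
                out_path: str | Path | None = None,
                precision: int = 1) -> ComparisonReport:
    """Assemble the apo/holo comparison report from two analysis bundles."""
    apo = _load_summary(apo_bundle)
    holo = _load_summary(holo_bundle)
    if apo["domains"] != holo["domains"]:
        raise ConfigError(
            f"incompatible domain maps: {apo['domains']} vs {holo['domains']}")

    decomposition = []
    for dom in apo["domains"]:
        ok = f"rmsd_overall_{dom}"
        ik = f"rmsd_intra_{dom}"
        if ok in apo["series"] and ok in holo["series"]:
            overall = holo["series"][ok]["mean"] - apo["series"][ok]["mean"]
            intra = holo["series"][ik]["mean"] - apo["series"][ik]["mean"]
            decomposition.append(geometry.DecompositionResult(
                domain=dom, overall_diff=overall, intra_diff=intra))

    comparisons = []
    for key in sorted(set(apo["series"]) & set(holo["series"])):
        a, h = apo["series"][key], holo["series"][key]
        comparisons.append(geometry.StateComparison(
            metric=key, apo_mean=a["mean"], apo_sd=a["sd"],
            holo_mean=h["mean"], holo_sd=h["sd"]))

    switch = None
    if all(dom in apo.get("clouds", {}) and dom in holo.get("clouds", {})
           for dom in ("AB", "SI")):
        ab_apo = _summary_from_dict(apo["clouds"]["AB"])
        ab_holo = _summary_from_dict(holo["clouds"]["AB"])
        si_apo = _summary_from_dict(apo["clouds"]["SI"])
        si_holo = _summary_from_dict(holo["clouds"]["SI"])
        switch = sampling.SwitchReport(
            ab_apo=ab_apo, ab_holo=ab_holo, si_apo=si_apo, si_holo=si_holo,
            switch_score=sampling.bidds_switch_score(ab_apo, ab_holo,
                                                     si_apo, si_holo))

    contact_means = {}
    for group in sorted(set(apo.get("contacts", {})) & set(holo.get("contacts", {}))):
        contact_means[group] = {"apo": apo["contacts"][group]["mean"],
                                "holo": holo["contacts"][group]["mean"]}
    sse_deltas = {}
    for dom in sorted(set(apo.get("sse", {})) & set(holo.get("sse", {}))):
        sse_deltas[dom] = {lab: holo["sse"][dom][lab] - apo["sse"][dom][lab]
                           for lab in "HEC"}
    cluster_counts = {}
    community_counts = {}
    for label, s in (("apo", apo), ("holo", holo)):
        if "clusters" in s:
            cluster_counts[label] = s["clusters"]["n_clusters"]
        if "communities" in s:
            community_counts[label] = s["communities"]["n_communities"]

    report = ComparisonReport(
        decomposition=decomposition, state_comparisons=comparisons,
        switch=switch, contact_means=contact_means, sse_deltas=sse_deltas,
        cluster_counts=cluster_counts, community_counts=community_counts)
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report_to_dict(report, precision), fh, sort_keys=True, indent=1)
    return report


def report_to_dict(report: ComparisonReport, precision: int = 1) -> dict:
    """JSON-ready view of a comparison report.

    Å quantities are rounded to ``precision`` decimals (matching the field's
    reporting style); dimensionless scores to 3; raw full-precision values
    are kept alongside under ``raw``.
    """
    p = precision

    def r(x):
        return round(float(x), p)

    d: dict = {"units": "Å", "decomposition": {}, "state_comparisons": {},
               "raw": {"decomposition": {}, "state_comparisons": {}}}
    for dec in report.decomposition:
        d["decomposition"][dec.domain] = {
            "overall_diff": r(dec.overall_diff), "intra_diff": r(dec.intra_diff),
            "inter_diff": r(dec.inter_diff)}
        d["raw"]["decomposition"][dec.domain] = {
            "overall_diff": dec.overall_diff, "intra_diff": dec.intra_diff,
            "inter_diff": dec.inter_diff}
    for c in report.state_comparisons:
        d["state_comparisons"][c.metric] = {
            "apo_mean": r(c.apo_mean), "apo_sd": r(c.apo_sd),
            "holo_mean": r(c.holo_mean), "holo_sd": r(c.holo_sd),
            "signed_diff": r(c.signed_diff), "abs_diff": r(c.abs_diff)}
        d["raw"]["state_comparisons"][c.metric] = {
            "apo_mean": c.apo_mean, "holo_mean": c.holo_mean,
            "signed_diff": c.signed_diff}
    if report.switch is not None:
        d["switch"] = {
            "score": round(report.switch.switch_score, 3),
            "ab_trace_apo": report.switch.ab_apo.covariance_trace,
            "ab_trace_holo": report.switch.ab_holo.covariance_trace,
            "si_trace_apo": report.switch.si_apo.covariance_trace,
            "si_trace_holo": report.switch.si_holo.covariance_trace,
        }
    d["contacts"] = {g: {k: round(v, 2) for k, v in m.items()}
                     for g, m in report.contact_means.items()}
    d["sse_deltas"] = {dom: {lab: round(v, 4) for lab, v in m.items()}
                       for dom, m in report.sse_deltas.items()}
    d["cluster_counts"] = report.cluster_counts
    d["community_counts"] = report.community_counts
    return d
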