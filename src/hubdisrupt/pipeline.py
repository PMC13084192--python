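"""End-to-end orchestration: cohort -> networks -> metrics -> HDI -> report.

A run either generates a synthetic cohort from a :class:`~hubdisrupt.cohort.
CohortSpec` or reads subject time-series files from an ``NC/`` / ``EMCI/``
directory pair.  For every subject and every sparsity it builds the binary
network and computes global and nodal metrics; hub-disruption indices for
the four nodal metrics are fitted against the control-group profile; the
group-level statistical report and abnormal-region tables are written as
TSV, and a provenance file (config, seed, version, per-file checksums)
makes reruns verifiable: identical config and seed reproduce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import Cohort, CohortSpec, generate_cohort, read_cohort, write_cohort
from .connectivity import (clean_matrix, binarize_by_sparsity, fisher_z,
                           pearson_connectivity, write_edge_list, write_matrix_tsv)
from .containers import NODAL_METRIC_NAMES, GlobalMetrics, NodalMetrics
from .hdi import cohort_hdi, hdi_table
from .metrics import all_metrics
from .stats import region_table, run_full_comparison

log = logging.getLogger(__name__)

DEFAULT_SPARSITIES = (0.2, 0.3, 0.4)


@dataclass
class RunConfig:
    """Declarative configuration of one full run."""

    input_mode: str = "synthetic"             # "synthetic" or "directory"
    cohort_spec: CohortSpec | None = None
    cohort_dir: str | None = None
    sparsities: tuple[float, ...] = DEFAULT_SPARSITIES
    primary_sparsity: float = 0.3
    alpha: float = 0.05
    alpha_strong: float = 0.01
    pooled_t: bool = False
    fdr: bool = False
    leave_one_out: bool = False
    include_intercept: bool = True
    top_k: int = 4
    out_dir: str = "hubdisrupt_out"
    seed: int = 0
    write_matrices: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "directory"):
            raise ValueError("input_mode must be 'synthetic' or 'directory'")
        for s in self.sparsities:
            if not (0 < s <= 1):
                raise ValueError(f"sparsity {s} outside (0, 1]")
        if self.primary_sparsity not in self.sparsities:
            raise ValueError("primary_sparsity must be one of sparsities")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a JSON config file; keyword arguments override file values."""
        data = json.loads(Path(path).read_text())
        data.update(overrides)
        if data.get("cohort_spec") is not None:
            data["cohort_spec"] = CohortSpec(**data["cohort_spec"])
        if "sparsities" in data:
            data["sparsities"] = tuple(data["sparsities"])
        return cls(**data)


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    global_metrics: dict[float, GlobalMetrics]   # by sparsity
    nodal_metrics: dict[float, NodalMetrics]


def analyze_cohort(cohort: Cohort, sparsities=DEFAULT_SPARSITIES) -> list[SubjectResult]:
    """Per-subject networks and metrics at every sparsity."""
    results = []
    for group, subjects in (("NC", cohort.nc_subjects), ("EMCI", cohort.emci_subjects)):
        for i, ts in enumerate(subjects, start=1):
            z = fisher_z(clean_matrix(pearson_connectivity(ts)))
            glob, nodal = {}, {}
            for s in sparsities:
                net = binarize_by_sparsity(z, s)
                glob[s], nodal[s] = all_metrics(net)
            results.append(SubjectResult(f"{group}_sub-{i:03d}", group, glob, nodal))
    return results


def _group(results: list[SubjectResult], group: str) -> list[SubjectResult]:
    return [r for r in results if r.group == group]


def cohort_hdi_values(
    results: list[SubjectResult],
    sparsity: float,
    include_intercept: bool = True,
    leave_one_out: bool = False,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], list, list]:
    """k-values per metric for both groups at one sparsity.

    Returns (NC k by metric, EMCI k by metric, NC HDIResults, EMCI
    HDIResults); both groups are scored against the NC profile.
    """
    nc = _group(results, "NC")
    em = _group(results, "EMCI")
    nc_nodal = [r.nodal_metrics[sparsity] for r in nc]
    em_nodal = [r.nodal_metrics[sparsity] for r in em]
    nc_k, em_k, nc_res, em_res = {}, {}, [], []
    for metric in NODAL_METRIC_NAMES:
        rs_nc = cohort_hdi(nc_nodal, nc_nodal, metric, sparsity,
                           subject_ids=[r.subject_id for r in nc],
                           include_intercept=include_intercept,
                           leave_one_out=leave_one_out)
        rs_em = cohort_hdi(nc_nodal, em_nodal, metric, sparsity,
                           subject_ids=[r.subject_id for r in em],
                           include_intercept=include_intercept,
                           leave_one_out=leave_one_out)
        nc_k[metric] = np.array([r.k for r in rs_nc])
        em_k[metric] = np.array([r.k for r in rs_em])
        nc_res += rs_nc
        em_res += rs_em
    return nc_k, em_k, nc_res, em_res


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> Path:
    """Execute all stages and write the artifact directory.

    Returns the output directory.  Raises on unreadable input, malformed
    subject files or label mismatches, naming the offending file.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_mode == "synthetic":
        spec = config.cohort_spec or CohortSpec(seed=config.seed)
        cohort = generate_cohort(spec)
        write_cohort(cohort, out / "cohort")
    else:
        if not config.cohort_dir:
            raise ValueError("directory mode requires cohort_dir")
        cohort = read_cohort(config.cohort_dir)

    results = analyze_cohort(cohort, config.sparsities)

    if config.write_matrices:
        mat_dir = out / "matrices"
        net_dir = out / "networks"
        mat_dir.mkdir(exist_ok=True)
        net_dir.mkdir(exist_ok=True)
        for group, subjects in (("NC", cohort.nc_subjects),
                                ("EMCI", cohort.emci_subjects)):
            for i, ts in enumerate(subjects, start=1):
                sid = f"{group}_sub-{i:03d}"
                z = fisher_z(clean_matrix(pearson_connectivity(ts)))
                write_matrix_tsv(z, mat_dir / f"{sid}_fisherz.tsv")
                net = binarize_by_sparsity(z, config.primary_sparsity)
                write_edge_list(net, net_dir / f"{sid}_edges.tsv")

    # metric tables
    import pandas as pd

    nodal_rows, global_rows = [], []
    for r in results:
        for s in config.sparsities:
            g = r.global_metrics[s]
            global_rows.append({"subject_id": r.subject_id, "group": r.group,
                                "sparsity": s, "L": g.L, "E_glob": g.E_glob,
                                "C": g.C,
                                "connected_pair_fraction": g.connected_pair_fraction})
            df = r.nodal_metrics[s].to_frame()
            df.insert(0, "sparsity", s)
            df.insert(0, "group", r.group)
            df.insert(0, "subject_id", r.subject_id)
            nodal_rows.append(df.rename_axis("region").reset_index())
    pd.DataFrame(global_rows).to_csv(out / "global_metrics.tsv", sep="\t",
                                     index=False, float_format="%.10g")
    pd.concat(nodal_rows, ignore_index=True).to_csv(
        out / "nodal_metrics.tsv", sep="\t", index=False, float_format="%.10g")

    # HDI tables and group comparisons
    hdi_frames = []
    hdi_by_sparsity = {}
    for s in config.sparsities:
        nc_k, em_k, nc_res, em_res = cohort_hdi_values(
            results, s, include_intercept=config.include_intercept,
            leave_one_out=config.leave_one_out)
        hdi_by_sparsity[s] = (nc_k, em_k)
        hdi_frames += [hdi_table(nc_res, "NC"), hdi_table(em_res, "EMCI")]
    pd.concat(hdi_frames, ignore_index=True).to_csv(
        out / "hdi.tsv", sep="\t", index=False, float_format="%.10g")

    global_by_sparsity = {
        s: ([r.global_metrics[s] for r in _group(results, "NC")],
            [r.global_metrics[s] for r in _group(results, "EMCI")])
        for s in config.sparsities
    }
    nodal_primary = (
        [r.nodal_metrics[config.primary_sparsity] for r in _group(results, "NC")],
        [r.nodal_metrics[config.primary_sparsity] for r in _group(results, "EMCI")],
    )
    report = run_full_comparison(global_by_sparsity, hdi_by_sparsity,
                                 nodal_at_primary=nodal_primary,
                                 top_k=config.top_k, pooled_t=config.pooled_t,
                                 fdr=config.fdr)
    report["comparison_table"].to_csv(out / "comparisons.tsv", sep="\t",
                                      index=False, float_format="%.10g")
    report["comparison_table"].to_json(out / "comparisons.json", orient="records",
                                       indent=1)
    for metric, diffs in report["abnormal_regions"].items():
        region_table(diffs).to_csv(out / f"abnormal_regions_{metric}.tsv",
                                   sep="\t", index=False, float_format="%.10g")

    # provenance: config + version + checksums of every written table
    prov = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "checksums": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*.tsv")) + sorted(out.rglob("*.json"))
            if p.name != "provenance.json"
        },
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=1))
    log.info("run complete: %s", out)
    return out


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("cohort_spec") is not None and not isinstance(d["cohort_spec"], dict):
        d["cohort_spec"] = dataclasses.asdict(d["cohort_spec"])
    return d
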