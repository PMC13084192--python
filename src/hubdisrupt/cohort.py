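"""Synthetic two-group ROI time-series cohorts with tunable hub disruption.

The generator emulates the *output* of a resting-state fMRI preprocessing
chain: per-subject multivariate time series (default 90 regions x 187 time
points, 45 + 45 subjects) drawn from group-level target correlation
matrices.  The control (NC) group's target has hub structure: a designated
set of hub regions whose pairwise correlations with every other region are
boosted above the baseline.  The patient (EMCI) group's target is the same
matrix with the hub excess shrunk by a disruption coefficient ``delta``,
and the removed correlation mass redistributed uniformly over
non-hub-incident pairs so that mean connectivity is matched across groups.
That compensation makes the downstream hub-disruption slope a
*reorganisation* signal (low-centrality regions rise while hubs fall), not
a global-strength signal.

Between-subject heterogeneity is additive Gaussian jitter on the
correlation entries followed by a positive-semidefinite repair — a direct
handle on the between-subject SD rather than a Wishart draw.  Samples are
i.i.d. multivariate normal; there is no hemodynamic forward model, no
temporal autocorrelation and no motion artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

from .atlas import aal90_labels
from .containers import ConnectivityMatrix, TimeSeriesMatrix

GROUPS = ("NC", "EMCI")

_PSD_FLOOR = 1e-8


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults mirror the target data regime: 90 atlas regions, 187 retained
    time points (197 scans minus 10 dropped for signal stabilisation),
    45 subjects per group.
    """

    n_nc: int = 45
    n_emci: int = 45
    n_regions: int = 90
    n_timepoints: int = 187
    n_hubs: int = 12
    hub_strength: float = 0.55       # pairwise r on hub-incident pairs
    base_strength: float = 0.15      # pairwise r on all other pairs
    disruption: float = 0.0          # delta >= 0: hub-excess shrink factor (EMCI)
    subject_noise_sd: float = 0.04   # per-subject jitter SD on r entries
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nc < 2 or self.n_emci < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not (0 < self.n_hubs < self.n_regions):
            raise ValueError("need 0 < n_hubs < n_regions")
        if not (0 <= self.base_strength < self.hub_strength < 1):
            raise ValueError("need 0 <= base_strength < hub_strength < 1")
        if self.disruption < 0:
            raise ValueError("disruption must be >= 0")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 time points")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be >= 0")

    @property
    def hub_indices(self) -> np.ndarray:
        """Hubs are the first ``n_hubs`` regions (a labelling choice only)."""
        return np.arange(self.n_hubs)

    def region_labels(self) -> list[str]:
        if self.n_regions == 90:
            return list(aal90_labels()["abbreviation"])
        return [f"R{i + 1:03d}" for i in range(self.n_regions)]


@dataclass
class Cohort:
    """A generated cohort plus the ground truth it was drawn from."""

    nc_subjects: list[TimeSeriesMatrix]
    emci_subjects: list[TimeSeriesMatrix]
    region_labels: list[str]
    truth: dict = field(default_factory=dict)


def psd_repair(m: np.ndarray, floor: float = _PSD_FLOOR) -> np.ndarray:
    """Clip negative eigenvalues to a small floor and renormalise to unit diagonal."""
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    if w.min() >= floor:
        out = m.copy()
    else:
        out = (v * np.maximum(w, floor)) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out


def make_group_correlation(spec: CohortSpec, group: str) -> ConnectivityMatrix:
    """Target correlation matrix for one group.

    NC: baseline ``base_strength`` everywhere, raised to ``hub_strength``
    on hub-incident pairs.  EMCI: the hub excess is multiplied by
    ``(1 - delta)`` and the removed total is spread uniformly over
    non-hub-incident pairs, preserving mean connectivity.  The result is
    PSD-repaired with a unit diagonal.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; allowed: {GROUPS}")
    n = spec.n_regions
    hubs = spec.hub_indices
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hubs] = True
    hub_incident = is_hub[:, None] | is_hub[None, :]
    np.fill_diagonal(hub_incident, False)

    m = np.full((n, n), spec.base_strength, dtype=float)
    excess = spec.hub_strength - spec.base_strength
    m[hub_incident] = spec.base_strength + excess

    if group == "EMCI" and spec.disruption > 0:
        removed_per_pair = spec.disruption * excess
        m[hub_incident] -= removed_per_pair
        n_hub_pairs = int(hub_incident.sum()) // 2
        off = ~np.eye(n, dtype=bool)
        non_hub = off & ~hub_incident
        n_non_hub_pairs = int(non_hub.sum()) // 2
        if n_non_hub_pairs > 0:
            bump = removed_per_pair * n_hub_pairs / n_non_hub_pairs
            # cap so entries stay strictly below 1 before repair
            bump = min(bump, 0.99 - spec.base_strength)
            m[non_hub] += bump
    np.fill_diagonal(m, 1.0)
    repaired = psd_repair(m)
    distortion = float(np.abs(repaired - m).max())
    if distortion > 1e-10:
        log.info("make_group_correlation(%s): PSD repair moved entries by "
                 "up to %.4f", group, distortion)
    return ConnectivityMatrix(repaired, kind="raw_r",
                              region_labels=spec.region_labels())


def simulate_subject_timeseries(
    target: ConnectivityMatrix,
    n_timepoints: int,
    noise_sd: float,
    seed: int,
) -> TimeSeriesMatrix:
    """Draw one subject's time series from a jittered target correlation.

    Symmetric Gaussian noise (SD ``noise_sd``) is added to the off-diagonal
    correlations, the matrix is PSD-repaired, and ``n_timepoints``
    independent zero-mean multivariate-normal samples are drawn from it.
    Deterministic given the seed.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    n = target.n_regions
    if n_timepoints < n:
        log.info(
            "n_timepoints (%d) < n_regions (%d): sample correlation will be "
            "rank-deficient", n_timepoints, n,
        )
    rng = np.random.default_rng(seed)
    m = target.values.copy()
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        m = np.clip(m + noise, -0.999, 0.999)
        np.fill_diagonal(m, 1.0)
    m = psd_repair(m)
    w, v = np.linalg.eigh(m)
    if w.min() < -1e-8:
        raise ValueError("correlation matrix not repairable to PSD")
    root = v * np.sqrt(np.maximum(w, 0.0))
    z = rng.standard_normal((n, n_timepoints))
    values = root @ z
    return TimeSeriesMatrix(values, region_labels=target.region_labels)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full two-group cohort, ground truth attached.

    Per-subject seeds are spawned from the master seed through a
    ``SeedSequence`` stream, so cohorts are reproducible bit-for-bit and
    each subject's draw is independent.
    """
    targets = {g: make_group_correlation(spec, g) for g in GROUPS}
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_nc + spec.n_emci
    child_seeds = ss.generate_state(n_total)
    subjects: dict[str, list[TimeSeriesMatrix]] = {"NC": [], "EMCI": []}
    for i in range(n_total):
        group = "NC" if i < spec.n_nc else "EMCI"
        ts = simulate_subject_timeseries(
            targets[group], spec.n_timepoints, spec.subject_noise_sd,
            seed=int(child_seeds[i]),
        )
        subjects[group].append(ts)
    truth = {
        "spec": dataclasses.asdict(spec),
        "hub_indices": spec.hub_indices.tolist(),
        "target_correlation": {g: targets[g].values for g in GROUPS},
    }
    return Cohort(
        nc_subjects=subjects["NC"],
        emci_subjects=subjects["EMCI"],
        region_labels=spec.region_labels(),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# directory layout: <out>/NC/sub-001.tsv, <out>/EMCI/sub-001.tsv, truth.json

def write_cohort(cohort: Cohort, out_dir: str | Path, header: bool = False) -> Path:
    """Write per-subject TSVs (regions as rows) and the ground-truth JSON."""
    out = Path(out_dir)
    for group, subjects in (("NC", cohort.nc_subjects), ("EMCI", cohort.emci_subjects)):
        gdir = out / group
        gdir.mkdir(parents=True, exist_ok=True)
        for i, ts in enumerate(subjects, start=1):
            path = gdir / f"sub-{i:03d}.tsv"
            with open(path, "w") as fh:
                if header:
                    fh.write("\t".join(ts.region_labels) + "\n")
                    np.savetxt(fh, ts.values.T, delimiter="\t", fmt="%.10g")
                else:
                    np.savetxt(fh, ts.values, delimiter="\t", fmt="%.10g")
    truth = dict(cohort.truth)
    if "target_correlation" in truth:
        truth["target_correlation"] = {
            g: np.asarray(m).tolist() for g, m in truth["target_correlation"].items()
        }
    truth["region_labels"] = cohort.region_labels
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return out


def read_cohort(cohort_dir: str | Path,
                region_labels: list[str] | None = None) -> Cohort:
    """Read a cohort back from the ``NC/`` / ``EMCI/`` directory layout."""
    from .connectivity import read_timeseries

    root = Path(cohort_dir)
    truth: dict = {}
    truth_path = root / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        if region_labels is None:
            region_labels = truth.get("region_labels")
    groups: dict[str, list[TimeSeriesMatrix]] = {}
    for group in GROUPS:
        gdir = root / group
        if not gdir.is_dir():
            raise FileNotFoundError(f"missing group directory: {gdir}")
        files = sorted(gdir.glob("*.tsv")) + sorted(gdir.glob("*.csv"))
        if not files:
            raise FileNotFoundError(f"no subject files under {gdir}")
        groups[group] = [
            read_timeseries(p, region_labels=region_labels,
                            sep="\t" if p.suffix == ".tsv" else ",")
            for p in files
        ]
    labels = region_labels or groups["NC"][0].region_labels
    return Cohort(nc_subjects=groups["NC"], emci_subjects=groups["EMCI"],
                  region_labels=list(labels), truth=truth)
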