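"""Synthetic cohort generator with planted tree topology and mediation chain.

Emulates a resting-state case-control connectomics cohort: two groups of
subjects (controls and patients), each subject carrying a ~164-node
connectivity matrix whose strongest edges form a planted spanning tree, and a
phenotype table with age, gender, head motion, medication, six cognitive test
scores and three symptom-domain scores.

Trees are drawn from a one-parameter path<->star continuum (``star_bias``):
each new node attaches to the current maximum-degree node with probability
``star_bias`` and otherwise extends the current path (attaches to the most
recently added node). ``star_bias = 0`` yields a pure path, ``star_bias = 1`` a
pure star, and the expected leaf fraction increases monotonically in between.

The phenotypes plant a mediation chain

    age --(a)--> star_bias --> leaf fraction --(b)--> negative symptom score
        \\------------------(c')-------------------------^

so the full pipeline (connectivity -> MST -> metrics -> mediation) is testable
end to end without any external data. Patients receive a ``star_bias`` offset,
giving the group difference in tree integration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, RoiTimeSeries
from .errors import GenerationError, InvalidSizeError
from .trees import SpanningTree, leaf_fraction

COGNITIVE_TESTS = (
    "wms_digit_span", "wms_symbol_span", "wms_letter_number",  # working memory
    "dkefs_verbal_fluency", "cpt_dprime", "stroop_conflict",   # executive function
)
SYMPTOM_SCORES = ("psychotic_symptom", "negative_symptom", "disorganization")

# per-group (control, patient) means and pooled SDs for the cognitive tests,
# mirroring a typical schizophrenia case-control battery
_TEST_MOMENTS = {
    "wms_digit_span": ((28.0, 23.0), 5.6),
    "wms_symbol_span": ((23.8, 17.3), 6.5),
    "wms_letter_number": ((19.8, 17.4), 2.9),
    "dkefs_verbal_fluency": ((39.9, 30.0), 9.7),
    "cpt_dprime": ((322.0, 317.5), 9.4),
    "stroop_conflict": ((0.98, 0.96), 0.04),
}


@dataclass
class CohortSpec:
    """Generative truths for one synthetic cohort.

    ``star_bias_age_slope`` is the a-path (star-bias units per SD of age),
    ``symptom_lf_slope`` the b-path and ``symptom_direct_age_slope`` the
    c'-path (both on the standardized scale of the negative-symptom score).
    """

    n_subjects_per_group: int = 40
    n_nodes: int = 164
    n_timepoints: int = 150
    age_range: tuple = (21.0, 55.0)
    star_bias_base: float = 0.40
    star_bias_group_offset: float = 0.15  # patients shifted toward star-like
    star_bias_age_slope: float = 0.10     # path a
    symptom_lf_slope: float = 0.50        # path b
    symptom_direct_age_slope: float = 0.0  # path c'
    noise_sd_topology: float = 0.05
    noise_sd_symptom: float = 0.8
    edge_strength: float = 0.6
    baseline: float = 0.1
    male_fraction: float = 29 / 40
    mode: str = "timeseries"  # "timeseries" or "connectivity"
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 4:
            raise InvalidSizeError("n_nodes must be >= 4")
        if self.n_subjects_per_group < 2:
            raise InvalidSizeError("need >= 2 subjects per group")
        if not 0 <= self.star_bias_base <= 1:
            raise GenerationError("star_bias_base must be in [0, 1]")
        if self.mode not in ("timeseries", "connectivity"):
            raise GenerationError(f"unknown mode {self.mode!r}")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str  # "control" | "patient"
    age: float
    gender: str  # "M" | "F"
    motion: float
    medication: float
    behavior_scores: dict
    planted_tree: SpanningTree
    data: object  # RoiTimeSeries or ConnectivityMatrix
    star_bias: float = 0.0
    star_bias_clipped: bool = False


def generate_tree_topology(n_nodes: int, star_bias: float, rng_seed) -> SpanningTree:
    """Grow a tree on the path<->star continuum by sequential attachment."""
    if n_nodes < 4:
        raise InvalidSizeError(f"n_nodes must be >= 4, got {n_nodes}")
    if not 0.0 <= star_bias <= 1.0:
        raise GenerationError(f"star_bias must be in [0, 1], got {star_bias}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    deg = np.zeros(n_nodes, dtype=int)
    edges = [(0, 1)]
    deg[0] = deg[1] = 1
    last = 1
    for i in range(2, n_nodes):
        if rng.random() < star_bias:
            target = int(np.argmax(deg[:i]))  # ties -> lowest index
        else:
            target = last
        edges.append((target, i))
        deg[target] += 1
        deg[i] = 1
        last = i
    return SpanningTree(list(range(n_nodes)), edges)


def tree_to_covariance(
    tree: SpanningTree, edge_strength: float = 0.6, baseline: float = 0.1,
    tol: float = 1e-6, max_shrink: int = 100,
) -> np.ndarray:
    """Correlation-like SPD matrix whose tree edges strictly dominate.

    Off-diagonals are ``edge_strength`` on tree edges and ``baseline``
    elsewhere; the matrix is shrunk toward the identity (which scales all
    off-diagonals uniformly, preserving the edge ordering) until the smallest
    eigenvalue exceeds ``tol``.
    """
    if not 0 <= baseline < edge_strength:
        raise GenerationError("need 0 <= baseline < edge_strength")
    n = tree.n
    index = {v: i for i, v in enumerate(tree.nodes)}
    sigma = np.full((n, n), baseline)
    np.fill_diagonal(sigma, 1.0)
    for u, v in tree.edges:
        i, j = index[u], index[v]
        sigma[i, j] = sigma[j, i] = edge_strength
    for _ in range(max_shrink):
        if np.linalg.eigvalsh(sigma).min() > tol:
            return sigma
        sigma = 0.9 * sigma + 0.1 * np.eye(n)
    raise GenerationError(
        f"could not reach positive definiteness within {max_shrink} shrinkage steps")


def _sample_timeseries(sigma: np.ndarray, t: int, rng: np.random.Generator) -> np.ndarray:
    chol = np.linalg.cholesky(sigma)
    return chol @ rng.standard_normal((sigma.shape[0], t))


def _roi_labels(n: int) -> list[str]:
    return [f"roi{i:03d}" for i in range(n)]


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Draw the full cohort; byte-identical output under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n_per = spec.n_subjects_per_group
    n_total = 2 * n_per
    groups = ["control"] * n_per + ["patient"] * n_per

    ages = rng.uniform(spec.age_range[0], spec.age_range[1], size=n_total)
    z_age = (ages - ages.mean()) / ages.std()

    n_male = int(round(spec.male_fraction * n_per))
    genders = (["M"] * n_male + ["F"] * (n_per - n_male)) * 2

    # head motion: lognormal framewise displacement, patients shifted upward
    def _lognorm(mean, sd_log, size):
        mu = np.log(mean) - sd_log**2 / 2
        return rng.lognormal(mu, sd_log, size)

    motion = np.concatenate([
        _lognorm(0.40, 0.30, n_per), _lognorm(0.58, 0.30, n_per)])
    medication = np.concatenate([
        np.zeros(n_per), _lognorm(350.0, 0.8, n_per)])

    # planted topology
    bias_raw = (
        spec.star_bias_base
        + spec.star_bias_group_offset * (np.array(groups) == "patient")
        + spec.star_bias_age_slope * z_age
        + rng.normal(0.0, spec.noise_sd_topology, n_total)
    )
    bias = np.clip(bias_raw, 0.0, 1.0)
    clipped = bias != bias_raw

    labels = _roi_labels(spec.n_nodes)
    trees, lfs = [], np.empty(n_total)
    for i in range(n_total):
        t_int = generate_tree_topology(spec.n_nodes, float(bias[i]), rng)
        tree = SpanningTree(labels, [(labels[u], labels[v]) for u, v in t_int.edges])
        trees.append(tree)
        lfs[i] = leaf_fraction(tree)
    z_lf = (lfs - lfs.mean()) / lfs.std() if lfs.std() > 0 else np.zeros(n_total)

    # symptoms: negative symptoms carry the planted b and c' paths (patients
    # only have ratings; the chain itself is generated for everyone and masked)
    negative = (
        spec.symptom_lf_slope * z_lf
        + spec.symptom_direct_age_slope * z_age
        + rng.normal(0.0, spec.noise_sd_symptom, n_total)
    )
    psychotic = rng.normal(0.0, 1.0, n_total)
    disorg = rng.normal(0.0, 1.0, n_total)

    # cognitive battery: within-domain shared latent + test noise, scaled to
    # group-specific means
    wm_latent = rng.normal(0.0, 1.0, n_total)
    ef_latent = rng.normal(0.0, 1.0, n_total)
    latents = {"wms_digit_span": wm_latent, "wms_symbol_span": wm_latent,
               "wms_letter_number": wm_latent,
               "dkefs_verbal_fluency": ef_latent, "cpt_dprime": ef_latent,
               "stroop_conflict": ef_latent}
    tests = {}
    for name, ((mu_c, mu_p), sd) in _TEST_MOMENTS.items():
        score_z = 0.7 * latents[name] + np.sqrt(1 - 0.7**2) * rng.normal(0, 1, n_total)
        mu = np.where(np.array(groups) == "patient", mu_p, mu_c)
        tests[name] = mu + sd * score_z

    subjects = []
    for i in range(n_total):
        gtag = "HC" if groups[i] == "control" else "SZ"
        sid = f"sub-{gtag}{(i % n_per) + 1:03d}"
        if spec.mode == "timeseries":
            sigma = tree_to_covariance(trees[i], spec.edge_strength, spec.baseline)
            data = RoiTimeSeries(sid, _sample_timeseries(sigma, spec.n_timepoints, rng),
                                 list(labels))
        else:
            sigma = tree_to_covariance(trees[i], spec.edge_strength, spec.baseline)
            z = np.arctanh(np.clip(sigma, -1 + 1e-7, 1 - 1e-7))
            np.fill_diagonal(z, 0.0)
            data = ConnectivityMatrix(sid, z, list(labels))
        behavior = {name: float(tests[name][i]) for name in COGNITIVE_TESTS}
        is_patient = groups[i] == "patient"
        behavior["psychotic_symptom"] = float(psychotic[i]) if is_patient else float("nan")
        behavior["negative_symptom"] = float(negative[i]) if is_patient else float("nan")
        behavior["disorganization"] = float(disorg[i]) if is_patient else float("nan")
        subjects.append(SyntheticSubject(
            subject_id=sid, group=groups[i], age=float(ages[i]),
            gender=genders[i], motion=float(motion[i]),
            medication=float(medication[i]), behavior_scores=behavior,
            planted_tree=trees[i], data=data,
            star_bias=float(bias[i]), star_bias_clipped=bool(clipped[i]),
        ))
    return subjects


def phenotype_table(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id, "group": s.group, "age": s.age,
               "gender": s.gender, "motion": s.motion, "medication": s.medication}
        row.update(s.behavior_scores)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(subjects: list[SyntheticSubject], outdir, spec: CohortSpec | None = None) -> dict:
    """Write per-subject matrices, phenotypes.csv, manifest.csv and the planted
    truth (tree edge lists, per-subject star_bias) as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    truth = {"subjects": {}}
    if spec is not None:
        truth["spec"] = {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in asdict(spec).items()}
    for s in subjects:
        fname = f"{s.subject_id}.tsv"
        mat = s.data.values if isinstance(s.data, RoiTimeSeries) else s.data.z
        kind = "timeseries" if isinstance(s.data, RoiTimeSeries) else "connectivity"
        np.savetxt(outdir / fname, mat, delimiter="\t", fmt="%.6g")
        manifest.append({"subject_id": s.subject_id, "file": fname, "kind": kind})
        truth["subjects"][s.subject_id] = {
            "star_bias": s.star_bias,
            "star_bias_clipped": s.star_bias_clipped,
            "tree_edges": [list(e) for e in s.planted_tree.edges],
        }
    phenotype_table(subjects).to_csv(outdir / "phenotypes.csv", index=False)
    pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return {"n_subjects": len(subjects), "outdir": str(outdir)}
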