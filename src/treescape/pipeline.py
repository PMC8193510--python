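"""End-to-end orchestration: connectivity -> MST -> metrics -> roles ->
similarity -> degree fits -> group tests -> mediation.

All randomness flows from a single root seed split per stage with
``numpy.random.SeedSequence``; a rerun with the same inputs, config and seed is
bit-identical for every deterministic output. Each run writes a
``run_report.json`` with a config hash, the per-stage seeds and timings, and
library versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectome import (ConnectivityMatrix, compute_connectivity, read_matrix,
                         read_timeseries, to_distance)
from .degree_fit import compare_fits, degree_histogram
from .errors import SchemaError, TreescapeError
from .inference import (covariate_adjusted_permutation_test, fdr_bh,
                        metric_intercorrelation, test_metric_table)
from .mediation import run_models
from .nodal import classify_roles, group_representative_mst, nodal_profiles
from .similarity import overlap_matrix, similarity_permutation_test
from .trees import SpanningTree, global_metrics, kruskal_mst

log = logging.getLogger("treescape")


@dataclass
class RunConfig:
    manifest: str = ""
    phenotypes: str = ""
    outdir: str = "treescape_out"
    n_perm_similarity: int = 10_000
    n_perm_group: int = 5_000
    n_boot: int = 5_000
    hub_sd_threshold: float = 2.0
    covariates: tuple = ("age", "gender", "motion")
    nodal_tests: bool = True
    mediation_models: tuple = (1, 2, 3, 4)
    seed: int = 0

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("outdir")  # analysis identity, not output location
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_subject_matrices(manifest_path) -> list[ConnectivityMatrix]:
    """Read the manifest and return one Fisher-z connectivity per subject.
    Time-series files are correlated and Fisher-z transformed on the fly."""
    manifest_path = Path(manifest_path)
    mf = pd.read_csv(manifest_path)
    if not {"subject_id", "file"}.issubset(mf.columns):
        raise SchemaError("manifest must have subject_id and file columns")
    base = manifest_path.parent
    out = []
    for _, row in mf.iterrows():
        path = base / row["file"]
        kind = row.get("kind", "connectivity")
        try:
            if kind == "timeseries":
                ts = read_timeseries(path, subject_id=row["subject_id"])
                out.append(compute_connectivity(ts))
            else:
                out.append(read_matrix(path, subject_id=row["subject_id"]))
        except Exception as exc:
            raise TreescapeError(
                f"stage=load subject={row['subject_id']} file={path}: {exc}") from exc
    return out


def subject_msts(matrices: list[ConnectivityMatrix]) -> list[SpanningTree]:
    trees = []
    for c in matrices:
        try:
            trees.append(kruskal_mst(to_distance(c)))
        except Exception as exc:
            raise TreescapeError(f"stage=mst subject={c.subject_id}: {exc}") from exc
    return trees


def metrics_table(trees: list[SpanningTree], subject_ids) -> pd.DataFrame:
    rows = []
    for sid, t in zip(subject_ids, trees):
        rec = {"subject_id": sid}
        rec.update(global_metrics(t).as_dict())
        rows.append(rec)
    return pd.DataFrame(rows)


def nodal_table(trees: list[SpanningTree], subject_ids) -> pd.DataFrame:
    """Per-subject, per-node degree and connector index (long format)."""
    rows = []
    for sid, t in zip(subject_ids, trees):
        for p in nodal_profiles(t):
            rows.append({"subject_id": sid, "node": p.node,
                         "degree": p.degree, "ci": p.ci})
    return pd.DataFrame(rows)


def nodal_group_tests(nt: pd.DataFrame, pheno: pd.DataFrame,
                      covariate_cols=("age", "gender", "motion"),
                      n_perm: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Per-node permutation tests on degree and ci, BH-corrected as a single
    family of (#nodes x 2) tests."""
    from .inference import _encode_covariates
    merged = nt.merge(pheno, on="subject_id")
    rows = []
    rng = np.random.default_rng(seed)
    for metric in ("degree", "ci"):
        for node, sub in merged.groupby("node", sort=True):
            y = sub[metric].to_numpy(dtype=float)
            cov = _encode_covariates(sub, covariate_cols) if covariate_cols else None
            r = covariate_adjusted_permutation_test(
                y, sub["group"].to_numpy(), cov, n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)), metric=f"{metric}:{node}")
            rows.append({"node": node, "metric": metric,
                         "observed": r.observed_stat, "p_raw": r.p_raw})
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_bh(out["p_raw"].to_numpy())
    return out


def write_tree_edgelist(t: SpanningTree, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tw\td\n")
        for u, v in t.edges:
            fh.write(f"{u}\t{v}\t{t.weights.get((u, v), '')}\t"
                     f"{t.distances.get((u, v), '')}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts under ``config.outdir``."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    stage_seed = {name: int(s.generate_state(1)[0] % (2**31 - 1))
                  for name, s in zip(
                      ("similarity", "group", "nodal", "mediation", "misc"), seeds)}
    report = {"config": asdict(config), "config_hash": config.config_hash(),
              "version": __version__, "stage_seeds": stage_seed,
              "numpy": np.__version__, "stages": {}}

    def _stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t_start": round(time.time() - t0, 3)}

    _stage("load")
    matrices = load_subject_matrices(config.manifest)
    pheno = pd.read_csv(config.phenotypes)
    ids = [c.subject_id for c in matrices]

    _stage("mst")
    trees = subject_msts(matrices)
    trees_dir = outdir / "trees"
    trees_dir.mkdir(exist_ok=True)
    for sid, t in zip(ids, trees):
        write_tree_edgelist(t, trees_dir / f"{sid}_mst.tsv")

    _stage("metrics")
    mt = metrics_table(trees, ids)
    mt.to_csv(outdir / "metrics.csv", index=False)
    metric_intercorrelation(mt).to_csv(outdir / "metric_intercorrelation.csv")

    _stage("roles")
    groups = pheno.set_index("subject_id").loc[ids, "group"]
    role_rows = []
    fits = {}
    rep_trees = {}
    for gname in sorted(groups.unique()):
        cohort = [c for c, g in zip(matrices, groups) if g == gname]
        rep = group_representative_mst(cohort)
        rep_trees[gname] = rep
        profs = classify_roles(nodal_profiles(rep), config.hub_sd_threshold)
        for p in profs:
            role_rows.append({"group": gname, "node": p.node, "degree": p.degree,
                              "bc": p.bc, "li": p.li, "ci": p.ci, "role": p.role})
        fits[gname] = {k: (v.as_dict() if hasattr(v, "as_dict") else v)
                       for k, v in _degree_report(rep).items()}
    pd.DataFrame(role_rows).to_csv(outdir / "nodal_roles.csv", index=False)
    with open(outdir / "degree_fits.json", "w") as fh:
        json.dump(fits, fh, indent=1)

    _stage("similarity")
    om = overlap_matrix(trees, ids)
    pd.DataFrame(om.sigma, index=ids, columns=ids).to_csv(outdir / "overlap_matrix.csv")
    sim = similarity_permutation_test(
        om, groups.to_numpy(), n_perm=config.n_perm_similarity,
        seed=stage_seed["similarity"])
    with open(outdir / "similarity_test.json", "w") as fh:
        json.dump({"observed": sim.observed_stat, "p": sim.p_value,
                   "n_perm": sim.n_permutations, "seed": sim.seed,
                   "group_means": sim.group_means, "group_sds": sim.group_sds,
                   "config_hash": config.config_hash()}, fh, indent=1)

    _stage("group_tests")
    gt = test_metric_table(mt.merge(pheno, on="subject_id"),
                           covariate_cols=config.covariates,
                           n_perm=config.n_perm_group, seed=stage_seed["group"])
    gt.to_csv(outdir / "group_tests_global.csv", index=False)
    if config.nodal_tests:
        nt = nodal_table(trees, ids)
        ngt = nodal_group_tests(nt, pheno, config.covariates,
                                n_perm=config.n_perm_group, seed=stage_seed["nodal"])
        ngt.to_csv(outdir / "group_tests_nodal.csv", index=False)

    _stage("mediation")
    med = {}
    for mid in config.mediation_models:
        med[f"model{mid}"] = run_models(mt, pheno, mid, n_boot=config.n_boot,
                                        seed=stage_seed["mediation"])
    with open(outdir / "mediation.json", "w") as fh:
        json.dump(med, fh, indent=1)

    report["elapsed_s"] = round(time.time() - t0, 3)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def _degree_report(rep_tree: SpanningTree) -> dict:
    h = degree_histogram(rep_tree)
    cmp = compare_fits(h)
    out = {f: cmp["fits"][f].as_dict() for f in cmp["fits"]}
    out["winner"] = cmp["winner"]
    out["partial"] = cmp["partial"]
    out["histogram"] = {"k": h.k.tolist(), "count": h.count.tolist()}
    return out
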