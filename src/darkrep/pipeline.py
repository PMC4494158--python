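"""End-to-end orchestration: simulate/load -> normalize -> profiles/PCA ->
modified-Dunnett calls -> classification -> report.

A run is fully described by a :class:`RunConfig` (exactly one input source:
a synthetic spec or a matrix/metadata path pair) and is deterministic under
a fixed seed.  Every run writes TSV/JSON artefacts plus a machine-readable
manifest (seed, parameters, per-stage row counts, output hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import (
    DARK,
    DARK_DBMIB,
    LIGHT,
    LIGHT_DBMIB,
    LIGHT_DCMU,
    SAMPLE_COLUMNS,
    SignalMatrix,
)
from .classify import attenuation_set, build_set, directional_overlap, summary_fractions
from .errors import ConfigurationError, StructuralError
from .io import ensure_dir, load_yaml, read_signal_matrix, write_signal_matrix, write_truth_table
from .mulcom import MulcomParams, call_regulated, mul_opt, permutation_fdr, _contrast_frame
from .normalize import compute_dx, normalize, pool_table
from .profiles import correlation_matrix, induction_ratio_correlation, pca, standard_profile_set
from .simulate import SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)

#: default quantiles of the observed max-|difference| statistic used to
#: build the m grid for mul_opt
DEFAULT_M_QUANTILES = (0.20, 0.25, 0.275, 0.30, 0.325, 0.35, 0.40, 0.50,
                       0.60, 0.75, 0.90)

#: default additive-stabiliser grid (normalized signal units; the light
#: time-0 pool is 1,000 over ~2,515 genes, so per-gene signals are O(0.4))
DEFAULT_T_GRID = (0.0, 0.02, 0.05, 0.1)


@dataclass
class RunConfig:
    synthetic: SyntheticSpec | None = None
    values_path: str | None = None
    meta_path: str | None = None
    outdir: str = "results/run"
    mulcom: MulcomParams = field(default_factory=MulcomParams)
    m_grid_quantiles: tuple = DEFAULT_M_QUANTILES
    t_grid: tuple = DEFAULT_T_GRID
    seed: int = 0

    def validate(self) -> None:
        has_paths = self.values_path is not None or self.meta_path is not None
        if (self.synthetic is None) == (not has_paths):
            raise ConfigurationError(
                "provide exactly one input source: a synthetic spec or "
                "values/meta paths")
        if has_paths and (self.values_path is None or self.meta_path is None):
            raise ConfigurationError("both values_path and meta_path are needed")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = load_yaml(path)
        synth = d.pop("synthetic", None)
        mp = d.pop("mulcom", None)
        cfg = cls(
            synthetic=SyntheticSpec.from_dict(synth) if synth else None,
            mulcom=MulcomParams(**mp) if mp else MulcomParams(),
            **{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()},
        )
        cfg.validate()
        return cfg


def default_m_grid(dx, test_conditions, control_condition=LIGHT,
                   quantiles=DEFAULT_M_QUANTILES) -> list[float]:
    """Data-driven m grid: quantiles of the per-gene max |mean difference|."""
    cf = _contrast_frame(dx, test_conditions, control_condition)
    obs = cf.absdiff().max(axis=0)
    return [float(np.quantile(obs, q)) for q in quantiles]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    outdir = ensure_dir(config.outdir)
    manifest: dict = {"seed": config.seed, "version": __version__, "stages": []}
    outputs: list[Path] = []

    def stage(name, rows, files):
        manifest["stages"].append({"name": name, "rows": int(rows),
                                   "outputs": [str(f.name) for f in files]})
        outputs.extend(files)

    # -- stage 1: input -----------------------------------------------------
    truth = None
    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        sm, truth = generate_dataset(spec)
        vp, mp_, tp = outdir / "signals.tsv", outdir / "samples.tsv", outdir / "truth.tsv"
        write_signal_matrix(sm, vp, mp_)
        write_truth_table(truth, tp)
        stage("simulate", len(sm.genes), [vp, mp_, tp])
        manifest["synthetic_spec"] = dataclasses.asdict(spec)
    else:
        sm = read_signal_matrix(config.values_path, config.meta_path)
        stage("load", len(sm.genes), [])

    # -- stage 2: normalization --------------------------------------------
    norm, factors = normalize(sm)
    dx = compute_dx(norm)
    pools = pool_table(norm)
    np_, pp = outdir / "normalized.tsv", outdir / "pools.tsv"
    norm.values.to_csv(np_, sep="\t", index_label="gene")
    pools.to_csv(pp, sep="\t", index=False)
    stage("normalize", len(norm.genes), [np_, pp])
    manifest["excluded_genes"] = len(factors.excluded_genes)

    # -- stage 3: profiles / PCA -------------------------------------------
    prof_conditions = [c for c in (LIGHT, DARK, LIGHT_DCMU, LIGHT_DBMIB)
                       if c in norm.conditions]
    prof = standard_profile_set(norm, conditions=prof_conditions)
    corr = correlation_matrix(prof)
    res = pca(corr)
    flat = corr.copy()
    flat.index = [f"{c}@{t}" for c, t in corr.index]
    flat.columns = flat.index
    cp = outdir / "profile_correlations.tsv"
    flat.to_csv(cp, sep="\t", index_label="profile")
    scores = res.scores.copy()
    scores.index = [f"{c}@{t}" for c, t in res.scores.index]
    sp = outdir / "pca_scores.tsv"
    scores.to_csv(sp, sep="\t", index_label="profile")
    vr = pd.DataFrame({"component": scores.columns,
                       "eigenvalue": res.eigenvalues,
                       "variance_fraction": res.variance_ratio})
    vp2 = outdir / "pca_variance.tsv"
    vr.to_csv(vp2, sep="\t", index=False)
    stage("profiles", corr.shape[0], [cp, sp, vp2])
    manifest["pc_variance_pct"] = [round(100 * v, 3) for v in res.variance_ratio[:2]]
    t_last = max(norm.times)
    manifest["induction_ratio_correlations"] = {
        f"dark_vs_{c}": induction_ratio_correlation(norm, DARK, c, t_last)
        for c in (LIGHT_DCMU, LIGHT_DBMIB) if c in norm.conditions}

    # -- stage 4: differential test ----------------------------------------
    # (m, t) are determined once, by mulOpt on the primary dark-vs-light
    # family, and then applied to every further comparison.
    base = dataclasses.replace(config.mulcom, seed=config.seed + 1)
    families = [c for c in (DARK, LIGHT_DCMU, LIGHT_DBMIB) if c in norm.conditions]
    grid_m = default_m_grid(dx, [families[0]],
                            quantiles=config.m_grid_quantiles)
    params = mul_opt(dx, grid_m, list(config.t_grid), base,
                     test_conditions=[families[0]])
    results = {}
    fdrs = {}
    for cond in families:
        fdrs[cond] = permutation_fdr(dx, params, test_conditions=[cond])
        results[cond] = call_regulated(dx, [cond], params)
    calls = pd.concat([r.calls for r in results.values()], ignore_index=True)
    contrasts = pd.concat([r.contrasts for r in results.values()],
                          ignore_index=True)
    cp2, kp = outdir / "mulcom_contrasts.tsv", outdir / "mulcom_calls.tsv"
    contrasts.to_csv(cp2, sep="\t", index=False)
    calls.to_csv(kp, sep="\t", index=False)
    stage("mulcom", len(calls), [cp2, kp])
    manifest["mulcom"] = {
        cond: {"m": results[cond].params.m, "t": results[cond].params.t,
               "fdr": fdrs[cond].fdr,
               "n_regulated": int(results[cond].calls["regulated"].sum())}
        for cond in families}

    # -- stage 5: classification -------------------------------------------
    sets = {cond: build_set(results[cond], cond) for cond in families}
    report: dict = {}
    if len(sets) >= 2:
        overlap = directional_overlap(list(sets.values()))
        regions = pd.DataFrame(
            [{"sets": "&".join(sorted(r)), "concordant": True, "count": c}
             for r, c in sorted(overlap.regions.items(), key=lambda kv: sorted(kv[0]))]
            + [{"sets": "&".join(sorted(r)), "concordant": False, "count": c}
               for r, c in sorted(overlap.discordant.items(),
                                  key=lambda kv: sorted(kv[0]))])
        op = outdir / "overlap_regions.tsv"
        regions.to_csv(op, sep="\t", index=False)
        og = outdir / "overlap_genes.tsv"
        overlap.members.to_csv(og, sep="\t", index=False)
    else:
        overlap, op, og = None, None, None
    if DARK_DBMIB in norm.conditions and DARK in sets:
        att_result = call_regulated(dx, [DARK_DBMIB], params,
                                    control_condition=DARK)
        att = attenuation_set(sets[DARK], att_result)
        report["attenuated"] = {
            "n": len(att), "of_dark_regulated": len(sets[DARK]),
            "pct_of_dark_regulated":
                100.0 * len(att) / max(1, len(sets[DARK]))}
        sets["dark-attenuated"] = att
    frac = summary_fractions(sets.values(), universe_size=len(norm.genes),
                             reference_label=DARK if DARK in sets else None)
    report["fractions"] = frac
    rp = outdir / "classification.json"
    rp.write_text(json.dumps(report, indent=2, sort_keys=True))
    files = [rp] + [f for f in (op, og) if f is not None]
    stage("classify", sum(len(s) for s in sets.values()), files)

    # -- stage 6: manifest ---------------------------------------------------
    manifest["classification"] = report
    manifest["outputs"] = {str(p.name): _sha256(p) for p in outputs}
    mp2 = outdir / "manifest.json"
    mp2.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["stages"].append({"name": "report", "rows": len(manifest["outputs"]),
                               "outputs": [mp2.name]})
    return manifest


# ---------------------------------------------------------------------------
# GEO series-matrix loading


def load_geo_series(path, sample_map) -> SignalMatrix:
    """Read a GEO series-matrix flat file into a SignalMatrix.

    ``sample_map`` maps deposited sample ids (column headers) to
    (condition, time_min, experiment); it may be a dict of tuples or a
    DataFrame indexed by sample id with those three columns.  Unmapped
    samples are reported and dropped.  The loader never invents values:
    genes are exactly the table's rows.
    """
    if isinstance(sample_map, pd.DataFrame):
        sample_map = {str(i): (r["condition"], int(r["time_min"]),
                               int(r["experiment"]))
                      for i, r in sample_map.iterrows()}
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines)
                   if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise StructuralError(
            "not a series-matrix file: table markers missing") from None
    from io import StringIO

    table = pd.read_csv(StringIO("\n".join(lines[start + 1:end])), sep="\t",
                        index_col=0)
    table.index.name = "gene"
    table.columns = [c.strip('"') for c in table.columns]
    unmapped = [c for c in table.columns if c not in sample_map]
    if unmapped:
        logger.warning("dropping %d unmapped sample(s): %s", len(unmapped),
                       ", ".join(unmapped[:5]))
    mapped = [c for c in table.columns if c in sample_map]
    if not mapped:
        raise StructuralError("sample map matches no sample in the file")
    meta = pd.DataFrame(
        [(c, *sample_map[c]) for c in mapped],
        columns=["sample_id", *SAMPLE_COLUMNS]).set_index("sample_id")
    return SignalMatrix(table[mapped], meta)
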