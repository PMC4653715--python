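"""End-to-end analysis stages over file-based inputs.

Each stage reads the standard inputs (TPS outlines, Newick tree, covariate
CSV) and/or intermediate CSVs from the output directory, runs one step of
the workflow, and writes CSV results.  Stochastic outputs embed the seed
and replicate counts as a leading ``#`` comment line; read them back with
``pandas.read_csv(..., comment="#")``.  The analysis set is always the
intersection of species codes across the supplied inputs; mismatches are
logged by name and dropped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import convergence as conv
from . import dtt as dttmod
from . import evomodels as evo
from . import geometry as geom
from . import groupstats, pgls, synthetic
from .io import (
    NUMERIC_COVARIATES,
    get_logger,
    read_covariates,
    read_newick,
    read_tps,
    stage_timer,
)
from .phylo import prune_to_taxa

log = get_logger("opermorph.pipeline")


def _write_csv(df: pd.DataFrame, path, meta: dict | None = None, index=False):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        df.to_csv(fh, index=index)
    log.info("wrote %s (%d rows)", path, len(df))


def stage_simulate(outdir, n_species=54, n_specimens=416, k=100, seed=0, **kw):
    """Write a synthetic study bundle (specimens.tps, tree.nwk, covariates.csv)."""
    with stage_timer("simulate", log):
        ds = synthetic.make_dataset(
            n_species=n_species, n_specimens=n_specimens, k=k, seed=seed, **kw
        )
        ds.write_bundle(outdir)
    return ds


def stage_align(tps_path, outdir, k=100, start=0):
    """Resample outlines to k semilandmarks and Procrustes-superimpose them.

    ``start=0`` (default) follows the digitizing convention that each traced
    outline begins at the homologous start landmark; pass
    ``start="curvature"`` to re-detect it from the dorsal curvature maximum.
    """
    with stage_timer("align", log):
        outlines = read_tps(tps_path)
        configs = [geom.resample_outline(o, k=k, start=start) for o in outlines]
        alignment = geom.gpa(configs)
        flat = alignment.flattened()
        cols = [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y")]
        df = pd.DataFrame(flat, columns=cols)
        df.insert(0, "centroid_size", alignment.centroid_sizes)
        df.insert(0, "species_code", alignment.species_codes)
        df.insert(0, "specimen_id", alignment.specimen_ids)
        _write_csv(df, Path(outdir) / "aligned.csv",
                   meta={"k": k, "iterations": alignment.iterations,
                         "converged": alignment.converged})
    return alignment


def _load_aligned(outdir):
    df = pd.read_csv(Path(outdir) / "aligned.csv", comment="#")
    coords = df.drop(columns=["specimen_id", "species_code", "centroid_size"]).to_numpy()
    n = len(df)
    return df, coords.reshape(n, -1, 2)


def stage_ordinate(outdir, species_level: bool = True):
    """Shape and form PCA (species means by default) plus broken-stick flags."""
    with stage_timer("ordinate", log):
        df, aligned = _load_aligned(outdir)
        alignment = geom.ProcrustesAlignment(
            aligned=aligned, mean_shape=aligned.mean(axis=0),
            centroid_sizes=df["centroid_size"].to_numpy(), iterations=0,
            converged=True, specimen_ids=list(df["specimen_id"]),
            species_codes=list(df["species_code"]),
        )
        if species_level:
            means, mean_cs = geom.species_mean_shapes(alignment)
            X = np.stack([m.coords for m in means])
            labels = [m.species_code for m in means]
            cs = np.array([mean_cs[sp] for sp in labels])
        else:
            X = aligned
            labels = list(df["specimen_id"])
            cs = alignment.centroid_sizes
        shape_space = geom.shape_pca(X.reshape(len(X), -1))
        form_space = geom.form_pca(X.reshape(len(X), -1), centroid_sizes=cs)
        for space, name in ((shape_space, "shape"), (form_space, "form")):
            scores = pd.DataFrame(
                space.scores[:, :10],
                columns=[f"PC{j + 1}" for j in range(min(10, space.n_axes))],
            )
            scores.insert(0, "species_code" if species_level else "specimen_id", labels)
            if name == "shape":
                scores["centroid_size"] = cs
            _write_csv(scores, Path(outdir) / f"{name}_scores.csv")
            expected, signif = geom.broken_stick(space.eigenvalues)
            eig = pd.DataFrame(
                {
                    "axis": np.arange(1, space.n_axes + 1),
                    "eigenvalue": space.eigenvalues,
                    "proportion": space.proportions,
                    "broken_stick": expected,
                    "significant": signif,
                }
            )
            _write_csv(eig, Path(outdir) / f"{name}_eigen.csv")
    return shape_space, form_space


def _species_table(outdir, covariates_path):
    scores = pd.read_csv(Path(outdir) / "shape_scores.csv", comment="#")
    cov = read_covariates(covariates_path)
    shared = [s for s in scores["species_code"] if s in set(cov.species)]
    dropped = sorted(set(scores["species_code"]) ^ set(cov.species))
    if dropped:
        log.warning("species not shared between scores and covariates: %s", dropped)
    merged = scores.set_index("species_code").join(cov.data.drop(columns="species_code"))
    return merged.loc[shared]


def stage_cva(outdir, covariates_path, factor="feeding_preference"):
    with stage_timer(f"cva[{factor}]", log):
        table = _species_table(outdir, covariates_path)
        pcs = [c for c in table.columns if c.startswith("PC")]
        model = groupstats.cva(table[pcs].to_numpy(), list(table[factor]))
        out = model.to_frame()
        out.insert(0, "species_code", list(table.index))
        _write_csv(out, Path(outdir) / f"cva_{factor}.csv")
        props = pd.DataFrame(
            {"axis": np.arange(1, len(model.cv_proportions) + 1),
             "percent_among_group": model.cv_proportions}
        )
        _write_csv(props, Path(outdir) / f"cva_{factor}_axes.csv")
    return model


def stage_panova(outdir, covariates_path, factor="feeding_preference",
                 n_perm=999, seed=0):
    """Procrustes ANOVA of specimen shapes and of ln CS by a species factor."""
    with stage_timer(f"panova[{factor}]", log):
        df, aligned = _load_aligned(outdir)
        cov = read_covariates(covariates_path)
        lab = df["species_code"].map(cov.data[factor])
        ok = lab.notna()
        if (~ok).any():
            log.warning("specimens without %s label dropped: %d", factor, (~ok).sum())
        rows = []
        for name, data in (
            ("shape", aligned[ok.to_numpy()]),
            ("log_cs", np.log(df.loc[ok, "centroid_size"].to_numpy())[:, None]),
        ):
            tab = groupstats.procrustes_anova(
                data, list(lab[ok]), n_perm=n_perm, seed=seed
            )
            rows.append(
                {"variable": name, "factor": factor, "F": tab.F,
                 "df_between": tab.df_between, "df_within": tab.df_within,
                 "P": tab.p_value, "SS_between": tab.SS_between,
                 "SS_within": tab.SS_within}
            )
        _write_csv(pd.DataFrame(rows), Path(outdir) / f"panova_{factor}.csv",
                   meta={"seed": seed, "n_perm": n_perm})
    return rows


def stage_pgls(outdir, tree_path, covariates_path):
    """PGLS of PC1, PC2 and centroid size against each ecological covariate."""
    with stage_timer("pgls", log):
        tree = read_newick(tree_path)
        table = _species_table(outdir, covariates_path)
        shared = [t for t in tree.tip_labels if t in table.index]
        dropped = sorted(set(tree.tip_labels) ^ set(table.index))
        if dropped:
            log.warning("species not shared with tree dropped: %s", dropped)
        tree = prune_to_taxa(tree, shared) if len(shared) < tree.n_tips else tree
        table = table.loc[shared]
        rows = []
        responses = ["PC1", "PC2", "centroid_size"]
        for resp in responses:
            for covar in NUMERIC_COVARIATES:
                if covar not in table.columns:
                    continue
                try:
                    res = pgls.PGLS(table[resp], table[[covar]], tree).fit()
                except ValueError as exc:
                    log.warning("PGLS %s ~ %s skipped: %s", resp, covar, exc)
                    continue
                rows.append(
                    {"response": resp, "covariate": covar, "n": res.n_used,
                     "beta": res.slope, "correlation": res.correlation,
                     "t": res.tvalues[1], "P": res.pvalues[1]}
                )
        out = pd.DataFrame(rows)
        _write_csv(out, Path(outdir) / "pgls.csv")
    return out


def _trait_frame(outdir, tree):
    scores = pd.read_csv(Path(outdir) / "shape_scores.csv", comment="#")
    scores = scores.set_index("species_code")
    shared = [t for t in tree.tip_labels if t in scores.index]
    dropped = sorted(set(tree.tip_labels) ^ set(scores.index))
    if dropped:
        log.warning("species without both tree and scores dropped: %s", dropped)
    tree = prune_to_taxa(tree, shared) if len(shared) < tree.n_tips else tree
    return scores.loc[shared], tree


def stage_fitmodels(outdir, tree_path, variables=("PC1", "PC2", "PC3", "centroid_size")):
    """Fit the six trait-evolution models per variable; Table-1-style matrix."""
    with stage_timer("fitmodels", log):
        tree = read_newick(tree_path)
        scores, tree = _trait_frame(outdir, tree)
        rows = []
        for var in variables:
            if var not in scores.columns:
                continue
            fits = [evo.fit_trait_model(scores[var], tree, model=m) for m in evo.MODELS]
            comp = evo.compare_models(fits)
            frame = comp.to_frame()
            frame.insert(0, "variable", var)
            rows.append(frame)
        out = pd.concat(rows, ignore_index=True)
        _write_csv(out, Path(outdir) / "model_comparison.csv")
    return out


def stage_signal(outdir, tree_path, variables=("PC1", "PC2", "PC3", "centroid_size"),
                 n_perm=999, seed=0):
    """Blomberg's K (permutation P) and Pagel's lambda; Table-2-style matrix."""
    with stage_timer("signal", log):
        tree = read_newick(tree_path)
        scores, tree = _trait_frame(outdir, tree)
        rows = []
        for var in variables:
            if var not in scores.columns:
                continue
            ks = evo.blomberg_k(scores[var], tree, n_perm=n_perm, seed=seed)
            lam = evo.pagel_lambda_signal(scores[var], tree)
            rows.append(
                {"variable": var, "K": ks.K, "K_P": ks.p_value,
                 "lambda": lam.lambda_hat, "lambda_lnL": lam.lnL_lambda}
            )
        out = pd.DataFrame(rows)
        _write_csv(out, Path(outdir) / "signal.csv",
                   meta={"seed": seed, "n_perm": n_perm})
    return out


def stage_converge(outdir, tree_path, exclude=(), n_pcs=3, n_sims=1000,
                   n_boot=1000, seed=0):
    with stage_timer("converge", log):
        tree = read_newick(tree_path)
        scores, tree = _trait_frame(outdir, tree)
        pcs = [f"PC{j + 1}" for j in range(n_pcs)]
        result = conv.distance_contrast_analysis(
            scores[pcs], tree, exclude=exclude, n_sims=n_sims,
            n_boot=n_boot, seed=seed,
        )
        _write_csv(result.to_frame(), Path(outdir) / "convergence.csv",
                   meta={"seed": seed, "n_sims": n_sims, "n_boot": n_boot,
                         "n_pcs": n_pcs})
    return result


def stage_dtt(outdir, tree_path, variables=("PC1", "centroid_size"),
              n_sims=1000, cutoff=0.9, seed=0):
    with stage_timer("dtt", log):
        tree = read_newick(tree_path)
        scores, tree = _trait_frame(outdir, tree)
        results = {}
        for var in variables:
            if var not in scores.columns:
                continue
            res = dttmod.mdi(scores[var], tree, n_sims=n_sims, cutoff=cutoff,
                             seed=seed)
            _write_csv(res.to_frame(), Path(outdir) / f"dtt_{var}.csv",
                       meta={"seed": seed, "n_sims": n_sims, "cutoff": cutoff,
                             "MDI": f"{res.MDI:.6f}", "P": f"{res.p_value:.6g}"})
            results[var] = res
    return results


def run_pipeline(config: dict) -> dict:
    """Run the full workflow from a flat configuration mapping.

    Recognized keys (all optional, with defaults): outdir, tps, tree, csv,
    k, n_species, n_specimens, n_perm, n_sims, n_boot, cutoff, seed,
    exclude (comma-separated species codes).  When tps/tree/csv are absent a
    synthetic bundle is generated into outdir first.
    """
    outdir = Path(config.get("outdir", "opermorph_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    k = int(config.get("k", 100))
    if not all(key in config for key in ("tps", "tree", "csv")):
        stage_simulate(
            outdir,
            n_species=int(config.get("n_species", 54)),
            n_specimens=int(config.get("n_specimens", 416)),
            k=k,
            seed=seed,
        )
        config = {**config, "tps": outdir / "specimens.tps",
                  "tree": outdir / "tree.nwk", "csv": outdir / "covariates.csv"}
    n_perm = int(config.get("n_perm", 999))
    n_sims = int(config.get("n_sims", 1000))
    n_boot = int(config.get("n_boot", 1000))
    cutoff = float(config.get("cutoff", 0.9))
    exclude = [s for s in str(config.get("exclude", "")).split(",") if s]

    stage_align(config["tps"], outdir, k=k)
    stage_ordinate(outdir)
    results = {}
    for factor in ("feeding_preference", "feeding_mode"):
        results[f"cva_{factor}"] = stage_cva(outdir, config["csv"], factor=factor)
        results[f"panova_{factor}"] = stage_panova(
            outdir, config["csv"], factor=factor, n_perm=n_perm, seed=seed
        )
    results["pgls"] = stage_pgls(outdir, config["tree"], config["csv"])
    results["models"] = stage_fitmodels(outdir, config["tree"])
    results["signal"] = stage_signal(outdir, config["tree"], n_perm=n_perm, seed=seed)
    results["convergence"] = stage_converge(
        outdir, config["tree"], exclude=exclude, n_sims=n_sims,
        n_boot=n_boot, seed=seed,
    )
    results["dtt"] = stage_dtt(outdir, config["tree"], n_sims=n_sims,
                               cutoff=cutoff, seed=seed)
    return results
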