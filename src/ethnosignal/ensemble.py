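"""Ensemble aggregation, significance rules, and tabular reports.

Every per-tree statistic (D, Faith's PD, PD percent, MNTD and its p-value)
can be run across a posterior tree ensemble; results are summarized as the
median and range over trees.  Significance of phylogenetic signal follows
tree-fraction rules: the trait is significantly non-random ("*") when at
least 95% of trees give p(D < 1) < 0.05, and "***" when every tree gives
p(D < 1) < 0.005.  The strength of the signal (its closeness to the
Brownian expectation) is graded by the fraction f of trees with
p(D > 0) > 0.05: weak (f < 0.90), moderate (0.90 <= f < 0.95), strong
(0.95 <= f < 1) and very strong (f = 1).  Boundary conventions — "95%"
inclusive, "all" meaning exactly 1 — are fixed here in one place.

Per-tree random seeds are derived from the master seed, the tree index and
a stable hash of the category name, so adding a category never perturbs
another category's results.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import dstat, phylodiversity
from .tree_io import PhyloTree, TreeEnsemble
from .use_records import TraitTable

__all__ = [
    "EnsembleSummary",
    "derive_seed",
    "run_metric_over_ensemble",
    "aggregate_median_range",
    "classify_significance",
    "classify_strength",
    "summarize_dstat",
    "summarize_values",
    "make_report",
]

METRICS = ("dstat", "faith_pd", "pd_percent", "mntd", "mntd_pvalue")

#: Response-class categories are appended after the alphabetized EBDCS
#: categories in reports, in this order.
RESPONSE_ROW_ORDER = ("inflammatory_response", "no_inflammatory_response", "unknown")


def derive_seed(master_seed: int, tree_index: int, category: str) -> int:
    """Deterministic per-(tree, category) seed below 2**31."""
    tag = f"{master_seed}:{tree_index}:{category}".encode()
    return zlib.crc32(tag) & 0x7FFFFFFF


def aggregate_median_range(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, min, max) over non-NA values; error if none remain."""
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("no non-NA values to aggregate")
    return float(np.median(arr)), float(arr.min()), float(arr.max())


def classify_significance(p_lt1_values: Sequence[float]) -> str:
    """Tree-fraction significance flag for p(D < 1) values.

    "***" if every tree has p < 0.005; "*" if at least 95% have p < 0.05;
    "ns" otherwise.
    """
    arr = np.asarray(list(p_lt1_values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value list")
    if (arr < 0.005).all():
        return "***"
    if (arr < 0.05).mean() >= 0.95:
        return "*"
    return "ns"


def classify_strength(p_gt0_values: Sequence[float]) -> str:
    """Strength label from the fraction f of trees with p(D > 0) > 0.05:
    weak f < 0.90, moderate 0.90 <= f < 0.95, strong 0.95 <= f < 1,
    very strong f = 1."""
    arr = np.asarray(list(p_gt0_values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value list")
    f = (arr > 0.05).mean()
    if f < 0.90:
        return "weak"
    if f < 0.95:
        return "moderate"
    if f < 1.0:
        return "strong"
    return "very strong"


@dataclass
class EnsembleSummary:
    """Aggregate of one statistic for one category across the ensemble."""

    category: str
    statistic: str
    values: list[float | None]
    median: float
    vmin: float
    vmax: float
    n_trees: int
    n_effective: int
    n_members: int | None = None
    prevalence: float | None = None
    frac_p_lt1_05: float | None = None
    frac_p_lt1_005: float | None = None
    frac_p_gt0_05: float | None = None
    significance: str | None = None
    strength: str | None = None
    p_value_flag: str | None = None
    na_reason: str | None = None


def run_metric_over_ensemble(
    ensemble: TreeEnsemble,
    trait_table: TraitTable,
    metric: str,
    params: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One record per (tree, category) for the requested statistic.

    ``params`` forwards metric-specific options: ``n_perm``/``n_sim``/
    ``nodal`` for ``dstat``; ``include_root`` for the PD metrics;
    ``focal``/``pool``/``n_rand``/``conspecific_policy`` for the MNTD
    metrics (``focal`` and ``pool`` are tip-label sets; MNTD rows compare
    each table category against the focal set).  Categories that cannot be
    analysed (e.g. fewer than 2 members for D) yield NA rows with a reason.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    params = dict(params or {})
    records = []
    for i, tree in enumerate(ensemble):
        per_tree = _per_tree_records(tree, i, trait_table, metric, params, seed)
        records.extend(per_tree)
    return pd.DataFrame.from_records(
        records,
        columns=["tree", "category", "value", "p_lt1", "p_gt0", "p_value", "na_reason"],
    )


def _per_tree_records(tree, tree_index, table, metric, params, master_seed):
    rows = []
    if metric == "dstat":
        arrays = None
        for cat in table.categories:
            cat_seed = derive_seed(master_seed, tree_index, cat)
            states = table.matrix[cat]
            try:
                if arrays is None:
                    resolved = dstat.resolve_polytomies(
                        tree, derive_seed(master_seed, tree_index, "__resolve__")
                    )
                    arrays = dstat.TreeArrays(
                        resolved, nodal=params.get("nodal", "weighted")
                    )
                res = dstat.d_statistic(
                    arrays,
                    states.reindex(list(arrays.tip_labels)).to_numpy(),
                    n_perm=params.get("n_perm", 1000),
                    n_sim=params.get("n_sim", 1000),
                    seed=cat_seed,
                )
                rows.append((tree_index, cat, res.d, res.p_d_lt_1, res.p_d_gt_0, None, None))
            except dstat.InsufficientVariationError as exc:
                rows.append((tree_index, cat, None, None, None, None, str(exc)))
        return rows
    if metric in {"faith_pd", "pd_percent"}:
        fn = phylodiversity.faith_pd if metric == "faith_pd" else phylodiversity.pd_percent
        for cat in table.categories:
            members = table.members(cat)
            if not members:
                rows.append((tree_index, cat, None, None, None, None, "no members"))
                continue
            value = fn(tree, members, include_root=params.get("include_root", True))
            rows.append((tree_index, cat, value, None, None, None, None))
        return rows
    # MNTD metrics: each category compared against the focal tip set
    focal = set(params["focal"])
    policy = params.get("conspecific_policy", "include_zero")
    dist = phylodiversity.patristic_matrix(tree)
    for cat in table.categories:
        members = table.members(cat)
        if not members:
            rows.append((tree_index, cat, None, None, None, None, "no members"))
            continue
        if metric == "mntd":
            value = phylodiversity.mntd_between(dist, focal, members, policy)
            rows.append((tree_index, cat, value, None, None, None, None))
        else:
            pool = set(params.get("pool") or (focal | members))
            res = phylodiversity.mntd_pvalue(
                dist,
                focal,
                members,
                pool | members,
                n_rand=params.get("n_rand", 1000),
                seed=derive_seed(master_seed, tree_index, cat),
                conspecific_policy=policy,
            )
            rows.append((tree_index, cat, res.mntd, None, None, res.p_value, None))
    return rows


def summarize_dstat(
    per_tree: pd.DataFrame,
    trait_table: TraitTable | None = None,
) -> list[EnsembleSummary]:
    """Aggregate per-tree D results into per-category summaries with the
    tree-fraction significance flag and strength label."""
    out = []
    n_trees = per_tree["tree"].nunique()
    for cat, grp in per_tree.groupby("category", sort=True):
        ok = grp[grp["value"].notna()]
        n_members = prev = None
        if trait_table is not None and cat in trait_table.categories:
            n_members = int(trait_table.counts[cat])
            prev = float(trait_table.prevalence[cat])
        if ok.empty:
            out.append(
                EnsembleSummary(
                    category=cat, statistic="D", values=list(grp["value"]),
                    median=float("nan"), vmin=float("nan"), vmax=float("nan"),
                    n_trees=n_trees, n_effective=0,
                    n_members=n_members, prevalence=prev,
                    na_reason="; ".join(sorted(set(grp["na_reason"].dropna()))),
                )
            )
            continue
        med, lo, hi = aggregate_median_range(ok["value"])
        p_lt1 = ok["p_lt1"].to_numpy(dtype=float)
        p_gt0 = ok["p_gt0"].to_numpy(dtype=float)
        out.append(
            EnsembleSummary(
                category=cat,
                statistic="D",
                values=list(grp["value"]),
                median=med, vmin=lo, vmax=hi,
                n_trees=n_trees, n_effective=len(ok),
                n_members=n_members, prevalence=prev,
                frac_p_lt1_05=float((p_lt1 < 0.05).mean()),
                frac_p_lt1_005=float((p_lt1 < 0.005).mean()),
                frac_p_gt0_05=float((p_gt0 > 0.05).mean()),
                significance=classify_significance(p_lt1),
                strength=classify_strength(p_gt0),
            )
        )
    return out


def summarize_values(
    per_tree: pd.DataFrame,
    statistic: str,
    trait_table: TraitTable | None = None,
    alpha: float = 0.05,
) -> list[EnsembleSummary]:
    """Aggregate per-tree values (PD, PD%, MNTD) into median/range summaries.

    For MNTD-with-p-value records, the per-ensemble flag follows the study
    convention: similarity is significant only when at least 95% of trees
    give a p-value below ``alpha``.
    """
    out = []
    n_trees = per_tree["tree"].nunique()
    for cat, grp in per_tree.groupby("category", sort=True):
        ok = grp[grp["value"].notna()]
        n_members = prev = None
        if trait_table is not None and cat in trait_table.categories:
            n_members = int(trait_table.counts[cat])
            prev = float(trait_table.prevalence[cat])
        if ok.empty:
            out.append(
                EnsembleSummary(
                    category=cat, statistic=statistic, values=list(grp["value"]),
                    median=float("nan"), vmin=float("nan"), vmax=float("nan"),
                    n_trees=n_trees, n_effective=0,
                    n_members=n_members, prevalence=prev,
                    na_reason="; ".join(sorted(set(grp["na_reason"].dropna()))),
                )
            )
            continue
        med, lo, hi = aggregate_median_range(ok["value"])
        flag = None
        if ok["p_value"].notna().any():
            p = ok["p_value"].to_numpy(dtype=float)
            flag = "*" if (p < alpha).mean() >= 0.95 else "ns"
        out.append(
            EnsembleSummary(
                category=cat, statistic=statistic, values=list(grp["value"]),
                median=med, vmin=lo, vmax=hi,
                n_trees=n_trees, n_effective=len(ok),
                n_members=n_members, prevalence=prev,
                p_value_flag=flag,
            )
        )
    return out


def _pretty(category: str) -> str:
    return category.replace("_", " ").capitalize()


def _report_order(summaries: Iterable[EnsembleSummary]) -> list[EnsembleSummary]:
    """Alphabetical EBDCS categories first, response-class rows last."""
    response = {c: i for i, c in enumerate(RESPONSE_ROW_ORDER)}
    return sorted(
        summaries,
        key=lambda s: (s.category in response, response.get(s.category, -1), s.category),
    )


def make_report(
    summaries: Sequence[EnsembleSummary],
    out_dir: str | Path | None = None,
    name: str = "report",
) -> pd.DataFrame:
    """Render summaries as a signal table (N, Prevalence, Median, Range,
    p(D<1) flag, strength) or a similarity table (N, Prevalence, MNTD
    Median, Range, p-value flag), written as TSV and JSON when ``out_dir``
    is given.  Values print to 2 decimals; the range uses an en dash."""
    if not summaries:
        raise ValueError("no summaries to report")
    rows = []
    is_d = all(s.statistic == "D" for s in summaries)
    for s in _report_order(summaries):
        row = {
            "category": _pretty(s.category),
            "N": s.n_members if s.n_members is not None else "",
            "prevalence": f"{s.prevalence:.2f}" if s.prevalence is not None else "",
        }
        if s.n_effective == 0:
            row.update(median="NA", range="NA")
            row["p" if is_d else "p_value"] = f"NA ({s.na_reason})"
            if is_d:
                row["strength"] = "NA"
        else:
            row["median"] = f"{s.median:.2f}"
            row["range"] = f"{s.vmin:.2f}–{s.vmax:.2f}"
            if is_d:
                row["p"] = s.significance
                row["strength"] = s.strength
            else:
                row["p_value"] = s.p_value_flag or ""
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
        df.to_json(out_dir / f"{name}.json", orient="records", indent=2, force_ascii=False)
    return df


def run_study_analysis(
    trees_path: str | Path,
    records_path: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    focal_category: str = "inflammatory_response",
    outgroup: Sequence[str] = (),
    n_perm: int = 1000,
    n_sim: int = 1000,
    n_rand: int = 1000,
    n_hot_rand: int = 1000,
    conspecific_policy: str = "include_zero",
    max_trees: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Full screening pipeline on a tree ensemble plus a use-record table.

    Reads the ensemble, optionally prunes outgroup taxa, builds the level-1,
    level-2 and response-class trait tables, and emits four reports into
    ``out_dir``: per-category phylogenetic signal for level-1 categories
    (``signal_l1``), for level-2 medicinal plus response-class categories
    (``signal_l2``), between-category MNTD against the focal response
    category (``mntd``, null pool = focal species plus the medicines
    species), and hot nodes of the focal category on the majority-rule
    consensus tree (``hot_nodes``).
    """
    from . import hot_nodes as hn
    from . import tree_io, use_records

    ens = tree_io.read_tree_ensemble(trees_path)
    if outgroup:
        keep = ens.taxa - set(outgroup)
        ens = TreeEnsemble([tree_io.prune_to_taxa(t, keep) for t in ens])
    if max_trees is not None and len(ens) > max_trees:
        idx = np.random.default_rng(seed).choice(len(ens), size=max_trees, replace=False)
        ens = TreeEnsemble([ens[int(i)] for i in sorted(idx)])
    records = use_records.load_use_records(records_path)
    tips = sorted(ens.taxa)
    t_l1 = use_records.build_trait_table(records, "ebdcs_l1", tips)
    t_l2 = use_records.build_trait_table(records, "ebdcs_l2", tips)
    t_resp = use_records.build_trait_table(records, "response_class", tips)

    out: dict[str, pd.DataFrame] = {}
    d_l1 = run_metric_over_ensemble(
        ens, t_l1, "dstat", {"n_perm": n_perm, "n_sim": n_sim}, seed
    )
    out["signal_l1"] = make_report(summarize_dstat(d_l1, t_l1), out_dir, "signal_l1")

    # level-2 medicinal categories and the response classes in one table
    merged = TraitTable(
        matrix=pd.concat([t_l2.matrix, t_resp.matrix], axis=1), spec="l2+response"
    )
    d_l2 = run_metric_over_ensemble(
        ens, merged, "dstat", {"n_perm": n_perm, "n_sim": n_sim}, seed
    )
    out["signal_l2"] = make_report(summarize_dstat(d_l2, merged), out_dir, "signal_l2")

    focal = t_resp.members(focal_category) if focal_category in t_resp.categories else frozenset()
    if focal:
        medicines = (
            t_l1.members("medicines") if "medicines" in t_l1.categories else frozenset()
        )
        pool = set(focal) | set(medicines)
        mntd = run_metric_over_ensemble(
            ens,
            t_l2,
            "mntd_pvalue",
            {
                "focal": focal,
                "pool": pool,
                "n_rand": n_rand,
                "conspecific_policy": conspecific_policy,
            },
            seed,
        )
        out["mntd"] = make_report(
            summarize_values(mntd, "MNTD", t_l2), out_dir, "mntd"
        )
        consensus = tree_io.majority_consensus(ens)
        hot = hn.hot_node_test(
            consensus, focal, n_rand=n_hot_rand, seed=derive_seed(seed, 0, "hotnodes")
        )
        hot_df = hot.table.reset_index()
        out["hot_nodes"] = hot_df
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        hot_df.to_csv(Path(out_dir) / "hot_nodes.tsv", sep="\t", index=False)
    return out
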