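"""Repertoire summary statistics.

Aggregates clonotype tables into the standard summary artifacts of a TRB
repertoire survey: per-TRBJ usage with D-gene composition and CDR3 length
statistics, per-TRBV-subgroup usage with resolved-gene detail, a germline
gene census by subgroup and functionality, rearrangement-class accounting,
and (for simulated data) truth-based recovery reports.

The package also bundles transcriptions of the published horse splenic
survey (212 clonotypes over 12 TRBJ genes; 136 germline genes in 29
subgroups) as TSV reference tables, so the same aggregation code can
reproduce the printed arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .germline import Functionality, GeneType

__all__ = [
    "round_half_away",
    "usage_percentages",
    "weighted_mean_cdr3",
    "JUsageSummary",
    "VUsageSummary",
    "GermlineCensus",
    "RecoveryReport",
    "summarize_by_j",
    "summarize_by_v",
    "summarize_germline",
    "j_usage_from_table",
    "rearrangement_accounting",
    "resolved_totals",
    "join_truth",
    "recovery_report",
    "load_reference_j_usage",
    "load_reference_v_usage",
    "load_reference_census",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for all reported
    percentages; banker's rounding is never applied)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def usage_percentages(count: float, denominator: float, decimals: int = 1) -> float:
    """100 * count / denominator, rounded half away from zero."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round_half_away(100.0 * count / denominator, decimals)


def weighted_mean_cdr3(group_means: list[float], group_counts: list[int]) -> float:
    """Count-weighted mean CDR3 length, reported at two decimals.

    Invariant under any merging of groups that preserves counts and sums.
    """
    if len(group_means) != len(group_counts):
        raise ValueError("group_means and group_counts must have equal length")
    if any(c < 0 for c in group_counts):
        raise ValueError("counts must be non-negative")
    total = sum(group_counts)
    if total == 0:
        raise ValueError("total count is zero")
    value = sum(m * c for m, c in zip(group_means, group_counts)) / total
    return round_half_away(value, 2)


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------

def _load(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("equitrb.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", **kwargs)


def load_reference_j_usage() -> pd.DataFrame:
    """Per-TRBJ clonotype counts, D composition and CDR3 statistics of the
    published horse splenic survey."""
    return _load("j_usage_reference.tsv")


def load_reference_v_usage() -> pd.DataFrame:
    """Per-TRBV-subgroup clonotype counts with resolved member genes."""
    return _load("v_usage_reference.tsv", keep_default_na=False)


def load_reference_census() -> pd.DataFrame:
    """Germline gene census (subgroup x functionality) of the horse locus."""
    return _load("germline_census_reference.tsv")


# ---------------------------------------------------------------------------
# TRBJ usage (shape of the published Table of clonotypes by TRBJ gene)
# ---------------------------------------------------------------------------

@dataclass
class JUsageSummary:
    per_gene: pd.DataFrame      # one row per J gene
    totals: pd.DataFrame        # cluster rows + overall row

    def check(self) -> None:
        pg = self.per_gene
        if not (pg["d1"] + pg["d2"] + pg["nd"] == pg["clonotypes"]).all():
            raise AssertionError("per-row D composition does not sum to count")
        for _, row in self.totals.iterrows():
            sel = (pg if row["scope"] == "overall"
                   else pg[pg["cluster"] == row["cluster"]])
            for col in ("clonotypes", "d1", "d2", "nd"):
                if sel[col].sum() != row[col]:
                    raise AssertionError(f"total {col} != column sum")


def j_usage_from_table(per_gene: pd.DataFrame) -> JUsageSummary:
    """Attach cluster-level and overall totals to a per-J-gene table.

    Weighted CDR3 means are recomputed from the per-gene means and counts;
    ranges are the min/min and max/max of member rows with clonotypes.
    """
    per_gene = per_gene.copy()
    rows = []
    scopes = [(c, f"cluster{c}") for c in sorted(per_gene["cluster"].unique())]
    scopes.append((0, "overall"))
    for cluster, scope in scopes:
        sel = per_gene if scope == "overall" else per_gene[per_gene["cluster"] == cluster]
        used = sel[sel["clonotypes"] > 0]
        row = {
            "scope": scope, "cluster": cluster,
            "clonotypes": int(sel["clonotypes"].sum()),
            "d1": int(sel["d1"].sum()), "d2": int(sel["d2"].sum()),
            "nd": int(sel["nd"].sum()),
        }
        if len(used):
            row["mean_cdr3"] = weighted_mean_cdr3(
                list(used["mean_cdr3"]), list(used["clonotypes"]))
            row["cdr3_min"] = int(used["cdr3_min"].min())
            row["cdr3_max"] = int(used["cdr3_max"].max())
        else:
            row["mean_cdr3"] = np.nan
            row["cdr3_min"] = row["cdr3_max"] = np.nan
        rows.append(row)
    return JUsageSummary(per_gene=per_gene, totals=pd.DataFrame(rows))


def summarize_by_j(clonotypes: pd.DataFrame,
                   j_genes: list[str] | None = None) -> JUsageSummary:
    """Aggregate a clonotype table by TRBJ gene.

    Counts clonotypes, their D composition (TRBD1 / TRBD2 / not
    determined), the mean CDR3 length (two decimals) and its range, per J
    gene and with cluster / overall totals.  ``j_genes`` optionally fixes
    the row universe (genes without clonotypes keep zero rows).
    """
    names = list(j_genes) if j_genes is not None else sorted(
        clonotypes["j_call"].unique()) if len(clonotypes) else []
    rows = []
    for name in names:
        sel = clonotypes[clonotypes["j_call"] == name] if len(clonotypes) else clonotypes
        n = len(sel)
        row = {
            "j_gene": name,
            "cluster": _j_cluster_from_name(name),
            "clonotypes": n,
            "d1": int((sel["d_call"] == "TRBD1").sum()) if n else 0,
            "d2": int((sel["d_call"] == "TRBD2").sum()) if n else 0,
            "nd": int((sel["d_call"] == "ND").sum()) if n else 0,
            "mean_cdr3": round_half_away(sel["cdr3_length"].mean(), 2) if n else np.nan,
            "cdr3_min": int(sel["cdr3_length"].min()) if n else np.nan,
            "cdr3_max": int(sel["cdr3_length"].max()) if n else np.nan,
        }
        rows.append(row)
    per_gene = pd.DataFrame(rows, columns=[
        "j_gene", "cluster", "clonotypes", "d1", "d2", "nd",
        "mean_cdr3", "cdr3_min", "cdr3_max"])
    return j_usage_from_table(per_gene)


def _j_cluster_from_name(name: str) -> int:
    # TRBJ<cluster>-<position>
    try:
        return int(name.split("-")[0].replace("TRBJ", ""))
    except ValueError:
        return 0


def rearrangement_accounting(per_gene: pd.DataFrame) -> dict:
    """Intra / inter / trans accounting from a per-J usage table.

    Intra-cluster joins pair TRBD1 with cluster-1 Js or TRBD2 with
    cluster-2 Js; TRBD1 with a cluster-2 J is an inter-cluster joining and
    TRBD2 with a cluster-1 J a trans-rearrangement.  The intra percentage
    is reported over clonotypes with a recognizable D.
    """
    c1 = per_gene[per_gene["cluster"] == 1]
    c2 = per_gene[per_gene["cluster"] == 2]
    intra = int(c1["d1"].sum() + c2["d2"].sum())
    inter = int(c2["d1"].sum())
    trans = int(c1["d2"].sum())
    identified = intra + inter + trans
    return {
        "intra_count": intra,
        "inter_count": inter,
        "trans_count": trans,
        "d_identified": identified,
        "nd_count": int(per_gene["nd"].sum()),
        "intra_pct": usage_percentages(intra, identified, 1) if identified else np.nan,
        "inter_pct": usage_percentages(inter, identified, 1) if identified else np.nan,
        "trans_pct": usage_percentages(trans, identified, 1) if identified else np.nan,
        "d1_count": int(per_gene["d1"].sum()),
        "d2_count": int(per_gene["d2"].sum()),
    }


# ---------------------------------------------------------------------------
# TRBV usage (shape of the published Table of clonotypes by TRBV subgroup)
# ---------------------------------------------------------------------------

@dataclass
class VUsageSummary:
    per_subgroup: pd.DataFrame      # subgroup, clonotypes, resolved
    unassigned: int
    total_clonotypes: int
    total_resolved: int

    def check(self) -> None:
        pg = self.per_subgroup
        if int(pg["clonotypes"].sum()) != self.total_clonotypes:
            raise AssertionError("subgroup counts do not sum to total")
        for _, row in pg.iterrows():
            resolved = _parse_resolved(row["resolved"])
            if sum(resolved.values()) > row["clonotypes"]:
                raise AssertionError("resolved counts exceed subgroup count")


def _parse_resolved(text: str) -> dict[str, int]:
    if not text or (isinstance(text, float) and np.isnan(text)):
        return {}
    out = {}
    for part in str(text).split(";"):
        if part:
            name, count = part.rsplit(":", 1)
            out[name] = int(count)
    return out


def _format_resolved(counts: dict[str, int]) -> str:
    return ";".join(f"{k}:{v}" for k, v in counts.items())


def summarize_by_v(clonotypes: pd.DataFrame,
                   subgroups: list[str] | None = None) -> VUsageSummary:
    """Aggregate a clonotype table by TRBV subgroup.

    Clonotypes assigned at gene or subgroup tier are counted under their
    subgroup; gene-tier calls additionally populate the resolved breakdown.
    Unassigned clonotypes are counted separately.
    """
    assigned = clonotypes[clonotypes["v_tier"].isin(["gene", "subgroup"])] \
        if len(clonotypes) else clonotypes
    unassigned = len(clonotypes) - len(assigned)

    def subgroup_of(v_call: str) -> str:
        first = v_call.split(",")[0]
        return first.split("-")[0]

    counts: dict[str, int] = {}
    resolved: dict[str, dict[str, int]] = {}
    for _, row in assigned.iterrows():
        sg = subgroup_of(row["v_call"])
        counts[sg] = counts.get(sg, 0) + 1
        if row["v_tier"] == "gene":
            gene = row["v_call"]
            resolved.setdefault(sg, {})
            resolved[sg][gene] = resolved[sg].get(gene, 0) + 1
    names = subgroups if subgroups is not None else sorted(counts)
    rows = [{"subgroup": sg, "clonotypes": counts.get(sg, 0),
             "resolved": _format_resolved(resolved.get(sg, {}))}
            for sg in names]
    per_subgroup = pd.DataFrame(rows, columns=["subgroup", "clonotypes", "resolved"])
    total_resolved = sum(sum(r.values()) for r in resolved.values())
    return VUsageSummary(per_subgroup=per_subgroup, unassigned=unassigned,
                         total_clonotypes=int(per_subgroup["clonotypes"].sum()),
                         total_resolved=total_resolved)


def resolved_totals(v_usage: pd.DataFrame, census: pd.DataFrame,
                    resolve_single_members: bool = True) -> tuple[int, pd.DataFrame]:
    """Total of conclusively resolved member genes in a V usage table.

    Subgroups with a single germline member leave the resolved column
    blank in the published layout even though the gene identity is
    implied; with ``resolve_single_members`` those clonotypes count as
    resolved and are flagged ``implied`` in the returned detail table.
    """
    members = dict(zip(census["subgroup"], census["n_genes"]))
    total = 0
    detail = []
    for _, row in v_usage.iterrows():
        explicit = _parse_resolved(row["resolved"])
        n_explicit = sum(explicit.values())
        implied = 0
        if (resolve_single_members and not explicit and row["clonotypes"] > 0
                and members.get(row["subgroup"], 0) == 1):
            implied = int(row["clonotypes"])
        total += n_explicit + implied
        detail.append({"subgroup": row["subgroup"], "explicit": n_explicit,
                       "implied": implied})
    return total, pd.DataFrame(detail)


# ---------------------------------------------------------------------------
# germline census (shape of the published gene/functionality table)
# ---------------------------------------------------------------------------

@dataclass
class GermlineCensus:
    per_subgroup: pd.DataFrame
    totals: dict

    def check(self) -> None:
        pg = self.per_subgroup
        if not (pg["n_p"] + pg["n_f"] + pg["n_orf"] == pg["n_genes"]).all():
            raise AssertionError("per-row functionality does not sum to gene count")
        for col in ("n_genes", "n_p", "n_f", "n_orf"):
            if int(pg[col].sum()) != self.totals[col]:
                raise AssertionError(f"total {col} != column sum")


def summarize_germline(source) -> GermlineCensus:
    """Census of germline V genes by subgroup and functionality.

    ``source`` is either a list of :class:`GermlineGene` (the census is
    computed from their classifications) or an already aggregated
    DataFrame with columns subgroup / n_genes / n_p / n_f / n_orf (e.g.
    the packaged reference table); totals are recomputed either way.
    """
    if isinstance(source, pd.DataFrame):
        per_subgroup = source.copy()
    else:
        counts: dict[str, dict[str, int]] = {}
        for g in source:
            if g.gene_type is not GeneType.V:
                continue
            sg = g.subgroup or g.name
            d = counts.setdefault(sg, {"n_genes": 0, "n_p": 0, "n_f": 0, "n_orf": 0})
            d["n_genes"] += 1
            key = {Functionality.P: "n_p", Functionality.F: "n_f",
                   Functionality.ORF: "n_orf"}[g.functionality]
            d[key] += 1
        per_subgroup = pd.DataFrame(
            [{"subgroup": sg, **d} for sg, d in sorted(counts.items())],
            columns=["subgroup", "n_genes", "n_p", "n_f", "n_orf"])
    totals = {col: int(per_subgroup[col].sum())
              for col in ("n_genes", "n_p", "n_f", "n_orf")}
    return GermlineCensus(per_subgroup=per_subgroup, totals=totals)


# ---------------------------------------------------------------------------
# simulation recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    segments: pd.DataFrame      # segment, precision, recall
    confusion: pd.DataFrame     # truth class x called class counts

    def check(self) -> None:
        seg = self.segments
        ok = seg[["precision", "recall"]].apply(
            lambda s: s.dropna().between(0, 1).all())
        if not ok.all():
            raise AssertionError("precision/recall outside [0, 1]")


def join_truth(clonotypes: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Join pipeline clonotypes to simulator ground truth.

    Read ids carry their record id after the '|' separator; each clonotype
    is linked to the truth record supported by most of its reads (ties
    resolved lexicographically).  Raises when a clonotype has no resolvable
    truth link.
    """
    if not len(clonotypes):
        return clonotypes.assign(truth_id=pd.Series(dtype=str))

    def link(read_ids: str) -> str:
        ids = [r.split("|", 1)[1] for r in read_ids.split(";") if "|" in r]
        if not ids:
            raise ValueError("clonotype reads carry no truth link")
        counts = pd.Series(ids).value_counts()
        top = counts[counts == counts.max()].index
        return sorted(top)[0]

    out = clonotypes.copy()
    out["truth_id"] = out["read_ids"].map(link)
    return out.merge(truth, left_on="truth_id", right_on="record_id",
                     how="left", suffixes=("", "_truth"))


_CLASSES = ["intra", "inter", "trans"]


def recovery_report(clonotypes: pd.DataFrame, truth: pd.DataFrame) -> RecoveryReport:
    """Per-segment precision/recall and class confusion versus ground truth.

    Recall denominators are the productive truth records; precision
    denominators are the definite calls (gene-tier for V, non-ND for D).
    Undefined ratios (no calls made) are reported as NA.
    """
    joined = join_truth(clonotypes, truth)
    if truth["productive"].dtype == object:
        productive = truth[truth["productive"].astype(str) == "True"]
        prod_mask = joined["productive"].astype(str) == "True"
    else:
        productive = truth[truth["productive"]]
        prod_mask = joined["productive"].astype(bool)
    n_truth = len(productive)
    joined_prod = joined[prod_mask]

    def ratio(num: int, den: int) -> float:
        return num / den if den else np.nan

    def recalled(rows: pd.DataFrame, correct_mask) -> int:
        # unique productive truth records with at least one correct call
        return rows.loc[correct_mask, "truth_id"].nunique()

    rows = []
    v_gene_rows = joined[joined["v_tier"] == "gene"]
    v_prec = int((v_gene_rows["v_call"] == v_gene_rows["v_name"]).sum())
    vp = joined_prod[joined_prod["v_tier"] == "gene"]
    rows.append({"segment": "V_gene",
                 "precision": ratio(v_prec, len(v_gene_rows)),
                 "recall": ratio(recalled(vp, vp["v_call"] == vp["v_name"]),
                                 n_truth)})
    def sub_ok(df: pd.DataFrame) -> pd.Series:
        if not len(df):
            return pd.Series(dtype=bool)
        return df.apply(lambda r: r["v_subgroup"]
                        == r["v_call"].split(",")[0].split("-")[0], axis=1)

    v_sub_rows = joined[joined["v_tier"].isin(["gene", "subgroup"])]
    vsp = joined_prod[joined_prod["v_tier"].isin(["gene", "subgroup"])]
    rows.append({"segment": "V_subgroup",
                 "precision": ratio(int(sub_ok(v_sub_rows).sum()), len(v_sub_rows)),
                 "recall": ratio(recalled(vsp, sub_ok(vsp)), n_truth)})
    d_rows = joined[joined["d_call"] != "ND"]
    dp = joined_prod[joined_prod["d_call"] != "ND"]
    rows.append({"segment": "D",
                 "precision": ratio(int((d_rows["d_call"] == d_rows["d_name"]).sum()),
                                    len(d_rows)),
                 "recall": ratio(recalled(dp, dp["d_call"] == dp["d_name"]),
                                 n_truth)})
    rows.append({"segment": "J",
                 "precision": ratio(int((joined["j_call"] == joined["j_name"]).sum()),
                                    len(joined)),
                 "recall": ratio(recalled(joined_prod,
                                          joined_prod["j_call"] == joined_prod["j_name"]),
                                 n_truth)})

    confusion = pd.DataFrame(0, index=_CLASSES, columns=_CLASSES + ["unknown"])
    for _, row in joined.iterrows():
        t = row["rearrangement_class_truth"] if "rearrangement_class_truth" in row \
            else row["rearrangement_class"]
        c = row["rearrangement_class"]
        if t in _CLASSES and c in confusion.columns:
            confusion.loc[t, c] += 1
    return RecoveryReport(segments=pd.DataFrame(rows), confusion=confusion)
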