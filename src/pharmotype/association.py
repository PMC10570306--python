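"""Protein-factor association statistics, preranked enrichment, networks.

Three layers link the proteome to clinical factors:

* per-protein linear-model ANOVA of expression against a factor, optionally
  with a confounder partialled out (e.g. VAF with diagnosis as confounder),
  Benjamini-Hochberg adjusted across proteins;
* two-group Student's t-tests producing volcano tables (log2FC, p, signed
  -log10 p);
* preranked gene-set enrichment: the weighted Kolmogorov-Smirnov running-sum
  enrichment score with a gene-label permutation null, normalized enrichment
  scores and permutation p-values (implemented from scratch -- the statistic
  is part of this package's contract, not delegated);
* assembly of an association network: per factor the top-k proteins below an
  adjusted-p cutoff, significantly enriched pathways, and high-confidence
  physical-interaction edges among included proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pharmotype._rng import stream

_P_FLOOR = 1e-300


def _bh(p: pd.Series) -> pd.Series:
    adj = np.full(len(p), np.nan)
    ok = p.notna().to_numpy()
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.Series(adj, index=p.index)


def _signed_sig(sign: np.ndarray, p: np.ndarray) -> np.ndarray:
    return sign * -np.log10(np.clip(p, _P_FLOOR, 1.0))


# ---------------------------------------------------------------------------
# per-protein ANOVA
# ---------------------------------------------------------------------------

def _encode(series: pd.Series, categorical: bool) -> np.ndarray:
    if categorical:
        levels = sorted(series.unique())
        if len(levels) < 2:  # constant: contributes nothing beyond intercept
            return np.empty((len(series), 0))
        return np.column_stack([(series == lv).to_numpy(float)
                                for lv in levels[1:]])
    return series.to_numpy(float)[:, None]


def protein_factor_anova(
    matrix: pd.DataFrame,
    factor: pd.Series,
    confounder: pd.Series | None = None,
    categorical: bool | None = None,
) -> pd.DataFrame:
    """Per-protein F-test of the factor term in ``x_p ~ factor (+ confounder)``.

    The sign is the direction of the first factor level versus the rest
    (categorical) or of the slope (continuous); signed significance is
    sign * (-log10 raw p); BH adjustment is across proteins.
    """
    samples = [s for s in matrix.columns if s in factor.index
               and pd.notna(factor[s])]
    if confounder is not None:
        samples = [s for s in samples if pd.notna(confounder.get(s))]
    fac = factor.reindex(samples)
    if fac.nunique() < 2:
        raise ValueError("factor is constant")
    if categorical is None:
        categorical = not pd.api.types.is_numeric_dtype(fac)

    x = matrix[samples].to_numpy(float)
    n = len(samples)
    intercept = np.ones((n, 1))
    fac_cols = _encode(fac, categorical)
    conf_cols = np.empty((n, 0))
    if confounder is not None:
        conf = confounder.reindex(samples)
        conf_cols = _encode(conf, not pd.api.types.is_numeric_dtype(conf))
    reduced = np.hstack([intercept, conf_cols])
    full = np.hstack([reduced, fac_cols])

    rank_full = np.linalg.matrix_rank(full)
    collinear = rank_full < full.shape[1]
    if collinear:
        warnings.warn("factor collinear with confounder; p set to NA")

    def rss(design: np.ndarray) -> np.ndarray:
        q, _ = np.linalg.qr(design)
        proj = q.T @ x.T
        return (x.T**2).sum(axis=0) - (proj**2).sum(axis=0)

    df_num = fac_cols.shape[1]
    df_den = n - full.shape[1]
    if df_den <= 0:
        raise ValueError("not enough samples for the requested model")
    rss_r, rss_f = rss(reduced), rss(full)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    f_stat = np.clip(f_stat, 0.0, None)
    p = stats.f.sf(f_stat, df_num, df_den)
    zero_resid = rss_f <= 1e-12 * np.maximum(rss_r, 1.0)
    p = np.where(zero_resid & (rss_r - rss_f > 1e-12), _P_FLOOR, p)
    p = np.where(zero_resid & ~(rss_r - rss_f > 1e-12), 1.0, p)

    if categorical:
        levels = sorted(fac.unique())
        first = (fac == levels[0]).to_numpy()
        sign = np.sign(x[:, first].mean(axis=1) - x[:, ~first].mean(axis=1))
    else:
        # slope of the factor after partialling the confounder
        beta, *_ = np.linalg.lstsq(full, x.T, rcond=None)
        sign = np.sign(beta[reduced.shape[1]])
    if collinear:
        p = np.full_like(p, np.nan)

    out = pd.DataFrame({
        "protein": matrix.index,
        "statistic": f_stat,
        "p_value": p,
        "sign": sign,
    }).set_index("protein")
    out["p_adj"] = _bh(out["p_value"])
    out["signed_sig"] = _signed_sig(out["sign"].to_numpy(),
                                    out["p_value"].to_numpy())
    return out.reset_index()


# ---------------------------------------------------------------------------
# two-group t-tests (volcano tables)
# ---------------------------------------------------------------------------

def differential_t(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Per-protein two-sided pooled-variance t-test of A vs B with
    log2FC = mean(A) - mean(B) and signed -log10 p."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    xa = matrix[list(group_a)].to_numpy(float)
    xb = matrix[list(group_b)].to_numpy(float)
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    degenerate = (xa.var(axis=1) == 0) & (xb.var(axis=1) == 0)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)
    p = np.where(degenerate & (log2fc != 0), 1e-16, p)
    deg_t = np.where(log2fc == 0, 0.0, np.sign(log2fc) * np.finfo(float).max)
    t = np.where(degenerate, deg_t, t)
    out = pd.DataFrame({
        "protein": matrix.index,
        "log2fc": log2fc,
        "t": t,
        "p_value": p,
    })
    out["p_adj"] = _bh(out["p_value"])
    out["signed_sig"] = _signed_sig(np.sign(out["log2fc"].to_numpy()),
                                    out["p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# preranked GSEA (weighted KS with gene-label permutation null)
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    p_adj: float
    direction: str
    size: int
    leading_edge: list[str]


def _running_es(hits: np.ndarray, weights: np.ndarray) -> tuple[float, int, np.ndarray]:
    """ES, peak position and the running sum for one ranked hit vector."""
    n = hits.size
    k = int(hits.sum())
    hit_w = np.where(hits, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all-zero weights: fall back to unweighted hits
        hit_w = hits.astype(float)
        denom = float(k)
    running = np.cumsum(hit_w / denom - (~hits).astype(float) / (n - k))
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak, running


def gsea_preranked(
    ranked_stats: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked enrichment over a protein -> statistic ranking.

    The ranking is sorted descending (ties by |statistic| then protein ID);
    the enrichment score is the weighted Kolmogorov-Smirnov running-sum
    maximum deviation with hit weights |stat|^weight_exponent. The null draws
    ``n_perm`` random same-size gene sets; p = (1 + #{|ES_null| >= |ES|}) /
    (n_perm + 1); NES = ES / mean |ES_null| of matching sign. BH across sets.
    """
    stats_ = ranked_stats.dropna()
    ids = stats_.index.to_numpy(str)
    vals = stats_.to_numpy(float)
    order = np.lexsort((ids, -np.abs(vals), -vals))
    ids, vals = ids[order], vals[order]
    n = ids.size
    weights = np.abs(vals) ** weight_exponent
    pos = {p: i for i, p in enumerate(ids)}
    rng = stream(seed, "gsea")

    rows = []
    for name, members in sets.items():
        idx = np.array(sorted({pos[m] for m in members if m in pos}), int)
        k = idx.size
        if k == 0:
            warnings.warn(f"set {name!r}: no overlap with ranking, skipped")
            continue
        if not (min_size <= k <= max_size):
            continue
        hits = np.zeros(n, bool)
        hits[idx] = True
        es, peak, running = _running_es(hits, weights)

        null = np.empty(n_perm)
        for b in range(n_perm):
            h = np.zeros(n, bool)
            h[rng.choice(n, size=k, replace=False)] = True
            null[b], _, _ = _running_es(h, weights)
        p = (1.0 + float((np.abs(null) >= abs(es)).sum())) / (n_perm + 1.0)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        norm = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
        nes = es / norm if norm > 0 else 0.0
        if es >= 0:
            leading = [ids[i] for i in idx if i <= peak]
        else:
            leading = [ids[i] for i in idx if i >= peak]
        rows.append({"set_name": name, "es": es, "nes": float(nes),
                     "p_value": p, "direction": "positive" if es >= 0
                     else "negative", "size": int(k),
                     "leading_edge": leading})
    out = pd.DataFrame(rows, columns=["set_name", "es", "nes", "p_value",
                                      "direction", "size", "leading_edge"])
    if not out.empty:
        out["p_adj"] = _bh(out["p_value"])
        out["signed_sig"] = _signed_sig(
            np.where(out["es"] >= 0, 1.0, -1.0), out["p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# association network
# ---------------------------------------------------------------------------

def build_network(
    associations: dict[str, pd.DataFrame],
    enrichments: dict[str, pd.DataFrame],
    edges: pd.DataFrame,
    top_k: int = 20,
    alpha_adj: float = 0.001,
    pathway_alpha_adj: float = 0.05,
    score_min: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble factor/protein/pathway nodes and typed weighted edges.

    Per factor: protein nodes are the ``top_k`` proteins by adjusted p among
    those with adjusted p < ``alpha_adj``; pathway nodes are sets with
    adjusted p < ``pathway_alpha_adj``; interaction edges are restricted to
    included protein nodes with score > ``score_min``.
    """
    node_rows, edge_rows = [], []
    proteins_in: set[str] = set()
    for factor, table in associations.items():
        node_rows.append({"node": factor, "node_type": "factor"})
        hits = table[table["p_adj"] < alpha_adj].nsmallest(top_k, "p_adj")
        for rec in hits.itertuples():
            proteins_in.add(rec.protein)
            edge_rows.append({"source": factor, "target": rec.protein,
                              "edge_type": "factor-protein",
                              "weight": float(rec.signed_sig)})
    for factor, table in enrichments.items():
        if table.empty:
            continue
        sig = table[table["p_adj"] < pathway_alpha_adj]
        for rec in sig.itertuples():
            node_rows.append({"node": rec.set_name, "node_type": "pathway"})
            edge_rows.append({"source": factor, "target": rec.set_name,
                              "edge_type": "factor-pathway",
                              "weight": float(rec.signed_sig)})
    for p in sorted(proteins_in):
        node_rows.append({"node": p, "node_type": "protein"})
    inter = edges[(edges["score"] > score_min)
                  & edges["protein_a"].isin(proteins_in)
                  & edges["protein_b"].isin(proteins_in)]
    for rec in inter.itertuples():
        edge_rows.append({"source": rec.protein_a, "target": rec.protein_b,
                          "edge_type": "protein-protein",
                          "weight": float(rec.score)})
    nodes = pd.DataFrame(node_rows, columns=["node", "node_type"])
    nodes = nodes.drop_duplicates("node").reset_index(drop=True)
    edge_df = pd.DataFrame(edge_rows, columns=["source", "target",
                                               "edge_type", "weight"])
    if nodes[nodes["node_type"] == "protein"].empty:
        warnings.warn("no proteins passed the association cutoffs; "
                      "emitting an empty network")
    return nodes, edge_df


def to_networkx(nodes: pd.DataFrame, edge_df: pd.DataFrame):
    """Optional networkx view of an assembled association network."""
    import networkx as nx

    g = nx.Graph()
    for rec in nodes.itertuples():
        g.add_node(rec.node, node_type=rec.node_type)
    for rec in edge_df.itertuples():
        g.add_edge(rec.source, rec.target, edge_type=rec.edge_type,
                   weight=rec.weight)
    return g
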