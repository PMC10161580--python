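"""Result annotation, framework comparison, and tabular I/O.

Coordinates are 1-based inclusive on both the VCF and GFF3 side, so no
conversion happens anywhere in the package.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd

from .expression import CountMatrix, GENE_COLUMNS

logger = logging.getLogger(__name__)


def _pkg_version() -> str:
    try:
        return version("countqtl")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def config_hash(params: dict) -> str:
    """Stable 12-hex digest of a parameter mapping."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str, params: dict | None = None) -> None:
    """Write a TSV with a provenance comment header (version, config hash,
    every parameter)."""
    params = params or {}
    with open(path, "w") as fh:
        fh.write(f"# countqtl v{_pkg_version()}\n")
        fh.write(f"# config_hash={config_hash(params)}\n")
        for k in sorted(params):
            fh.write(f"# {k}={params[k]}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_counts_tsv(counts_path: str, genes_path: str | None = None) -> CountMatrix:
    """Read a genes x samples count TSV plus a gene-annotation sidecar.

    The count file has gene ids in the first column and sample ids in
    the header.  The sidecar carries ``id``, ``chrom``, ``start``,
    ``end``, ``exonic_length``, ``biotype``; without one, placeholder
    annotation is used (length filters then unavailable).
    """
    tab = pd.read_csv(counts_path, sep="\t", comment="#")
    gene_ids = tab.iloc[:, 0].astype(str)
    counts = tab.iloc[:, 1:].to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or np.any(counts < 0):
        raise ValueError("counts must be non-negative numbers")
    if genes_path is not None:
        genes = pd.read_csv(genes_path, sep="\t", comment="#")
        missing = set(GENE_COLUMNS) - set(genes.columns)
        if missing:
            raise ValueError(f"gene metadata missing columns: {sorted(missing)}")
        genes = genes.set_index("id").loc[gene_ids].reset_index()
    else:
        genes = pd.DataFrame({
            "id": gene_ids, "chrom": "NA", "start": 1, "end": 1,
            "exonic_length": 1_000, "biotype": "protein_coding",
        })
    return CountMatrix(genes=genes, samples=list(tab.columns[1:]),
                       counts=counts.astype(np.int64))


def write_counts_tsv(cm: CountMatrix, counts_path: str, genes_path: str | None = None) -> None:
    tab = pd.DataFrame(cm.counts, columns=cm.samples)
    tab.insert(0, "gene_id", cm.genes["id"])
    tab.to_csv(counts_path, sep="\t", index=False)
    if genes_path:
        cm.genes.to_csv(genes_path, sep="\t", index=False)


def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_genes(path: str) -> pd.DataFrame:
    """Gene features from a GFF3 file, with union-exon exonic lengths.

    Returns the standard gene-annotation frame (``id``, ``chrom``,
    ``start``, ``end``, ``exonic_length``, ``biotype``).  Exonic length
    is the length of the union of the gene's exon intervals; genes
    without exon children fall back to the gene span.
    """
    genes: list[dict] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    id_of_feature: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _, ftype, start, end, _, _, _, attrs = parts[:9]
            a = _gff3_attributes(attrs)
            if ftype == "gene":
                gid = a.get("gene_id") or a.get("ID", "").removeprefix("gene:")
                genes.append({
                    "id": gid, "chrom": chrom, "start": int(start), "end": int(end),
                    "biotype": a.get("biotype") or a.get("gene_biotype", "NA"),
                })
                id_of_feature[a.get("ID", gid)] = gid
            elif ftype in ("mRNA", "transcript"):
                parent = a.get("Parent", "")
                if parent in id_of_feature:
                    id_of_feature[a.get("ID", "")] = id_of_feature[parent]
            elif ftype == "exon":
                parent = a.get("Parent", "")
                gid = id_of_feature.get(parent)
                if gid is not None:
                    exons.setdefault(gid, []).append((int(start), int(end)))
    out = pd.DataFrame(genes)
    lengths = []
    for _, g in out.iterrows():
        ivs = sorted(exons.get(g["id"], [(g["start"], g["end"])]))
        total, cur_s, cur_e = 0, ivs[0][0], ivs[0][1]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        lengths.append(total + cur_e - cur_s + 1)
    out["exonic_length"] = lengths
    return out[GENE_COLUMNS]


def annotate_proximity(
    results: pd.DataFrame,
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 1_000,
) -> pd.DataFrame:
    """Annotate each result's variant with genes whose model it touches.

    A variant is annotated to a gene when its position lies within
    ``[start - flank, end + flank]`` on the same chromosome (1-based
    inclusive); all qualifying genes are listed nearest first, with
    distance 0 inside the gene model.
    """
    vtab = variants.set_index(variants["id"].fillna(
        variants["chrom"].astype(str) + ":" + variants["pos"].astype(str)
    ))
    known_chroms = set(genes["chrom"].astype(str))
    vcs = set(vtab["chrom"].astype(str))
    if known_chroms.isdisjoint(vcs) and len(vcs):
        warnings.warn(
            f"no chromosome overlap between variants ({sorted(vcs)[:3]}...) "
            f"and gene annotation ({sorted(known_chroms)[:3]}...)",
            stacklevel=2,
        )
    out = results.copy()
    nearby, nearest, neardist = [], [], []
    for vid in out["variant_id"]:
        if vid not in vtab.index:
            nearby.append("")
            nearest.append(None)
            neardist.append(np.nan)
            continue
        chrom, pos = str(vtab.at[vid, "chrom"]), int(vtab.at[vid, "pos"])
        sub = genes[genes["chrom"].astype(str) == chrom]
        dist = np.maximum(
            np.maximum(sub["start"].to_numpy() - pos, pos - sub["end"].to_numpy()), 0
        )
        hit = dist <= flank
        order = np.argsort(dist[hit], kind="mergesort")
        ids = sub.loc[hit, "id"].to_numpy()[order]
        nearby.append(",".join(ids))
        nearest.append(ids[0] if len(ids) else None)
        neardist.append(int(dist[hit][order][0]) if len(ids) else np.nan)
    out["nearby_genes"] = nearby
    out["nearest_gene"] = nearest
    out["nearest_distance"] = neardist
    out.attrs = dict(results.attrs)
    return out


def cis_trans_label(
    results: pd.DataFrame,
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Label each tested pair cis or trans.

    A pair is cis when the variant lies within ``window`` nt of the
    tested gene's span on the same chromosome (inclusive boundaries);
    otherwise trans.  Unknown gene coordinates give a null label with a
    warning.
    """
    gtab = genes.set_index("id")
    vtab = variants.set_index(variants["id"].fillna(
        variants["chrom"].astype(str) + ":" + variants["pos"].astype(str)
    ))
    labels = []
    unknown = 0
    for gid, vid in zip(results["gene_id"], results["variant_id"]):
        if gid not in gtab.index or vid not in vtab.index:
            labels.append(None)
            unknown += 1
            continue
        g = gtab.loc[gid]
        if str(vtab.at[vid, "chrom"]) != str(g["chrom"]):
            labels.append("trans")
            continue
        pos = int(vtab.at[vid, "pos"])
        labels.append(
            "cis" if g["start"] - window <= pos <= g["end"] + window else "trans"
        )
    if unknown:
        warnings.warn(f"{unknown} pair(s) with unknown gene coordinates", stacklevel=2)
    out = results.copy()
    out["cis_trans"] = labels
    out.attrs = dict(results.attrs)
    out.attrs["cis_window"] = window
    return out


def compare_frameworks(
    results_linear: pd.DataFrame,
    results_nb: pd.DataFrame,
    threshold: float = 5e-8,
):
    """Overlap of significant eQTLs between the two frameworks.

    Both inputs must cover the same gene x variant universe per shared
    model.  Returns ``(summary, pvp)``: per-model significant-set sizes,
    intersection size and Jaccard index, plus a p-vs-p table of every
    pair with both frameworks' p-values.
    """
    key_cols = ["gene_id", "variant_id"]
    uni_lin = set(map(tuple, results_linear[key_cols].drop_duplicates().to_numpy()))
    uni_nb = set(map(tuple, results_nb[key_cols].drop_duplicates().to_numpy()))
    if uni_lin != uni_nb:
        asym = sorted(uni_lin ^ uni_nb)[:10]
        raise ValueError(f"mismatched test universes; e.g. {asym}")

    def sig_set(df, model):
        sub = df[(df["model"] == model) & (df["p"] < threshold)]
        return set(map(tuple, sub[key_cols].to_numpy()))

    rows = []
    models = sorted(
        set(results_linear["model"].unique()) & set(results_nb["model"].unique())
    )
    for model in models:
        a, b = sig_set(results_linear, model), sig_set(results_nb, model)
        inter = a & b
        union = a | b
        rows.append({
            "model": model,
            "n_sig_linear": len(a), "n_sig_nb": len(b),
            "n_intersection": len(inter),
            "jaccard": len(inter) / len(union) if union else np.nan,
        })
    # framework-level overlap pooling all models
    a_all = set(map(tuple, results_linear.loc[results_linear["p"] < threshold, key_cols].to_numpy()))
    b_all = set(map(tuple, results_nb.loc[results_nb["p"] < threshold, key_cols].to_numpy()))
    union = a_all | b_all
    rows.append({
        "model": "any",
        "n_sig_linear": len(a_all), "n_sig_nb": len(b_all),
        "n_intersection": len(a_all & b_all),
        "jaccard": len(a_all & b_all) / len(union) if union else np.nan,
    })
    summary = pd.DataFrame(rows)

    pvp = pd.merge(
        results_linear.groupby(key_cols, as_index=False)["p"].min().rename(columns={"p": "p_linear"}),
        results_nb.groupby(key_cols, as_index=False)["p"].min().rename(columns={"p": "p_nb"}),
        on=key_cols,
    )
    pvp["neglog10_p_linear"] = -np.log10(pvp["p_linear"])
    pvp["neglog10_p_nb"] = -np.log10(pvp["p_nb"])
    return summary, pvp
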