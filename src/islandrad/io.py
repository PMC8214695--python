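"""Readers and writers for the pipeline's external formats.

Newick trees go through dendropy; climate tables and genotype matrices are
plain CSV via pandas; geography models are YAML or JSON; VCF genotypes go
through cyvcf2.  Every reader validates into the domain types in
:mod:`islandrad.datatypes` so downstream stages can assume the invariants.
"""

from __future__ import annotations

import json
import logging
import pathlib

import dendropy
import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    MISSING,
    ULTRAMETRIC_TOL,
    ClimateSeries,
    GenotypeMatrix,
    GeographyModel,
    TimeTree,
    ValidationError,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# trees


def _timetree_from_dendropy(tree: dendropy.Tree, stretch_tips: bool,
                            resolve_polytomies: bool) -> TimeTree:
    tree = tree.clone(depth=1)
    if resolve_polytomies:
        tree.resolve_polytomies()
        for e in tree.preorder_edge_iter():
            if e.head_node.parent_node is not None and not e.length:
                e.length = 1e-9
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            raise ValidationError("tree has edges without branch lengths")
        if nd.parent_node is not None and nd.edge.length < 0:
            raise ValidationError("negative branch length in tree")
        nkids = len(nd.child_nodes())
        if nkids not in (0, 2):
            raise ValidationError(
                f"non-binary node with {nkids} children; pass "
                "resolve_polytomies=True to auto-resolve"
            )
    # depths from the root
    depth = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[nd] = 0.0
        else:
            depth[nd] = depth[nd.parent_node] + nd.edge.length
    leaves = tree.leaf_nodes()
    maxd = max(depth[l] for l in leaves)
    if stretch_tips:
        for l in leaves:
            gap = maxd - depth[l]
            if gap > 0:
                l.edge.length += gap
                depth[l] = maxd
    labels = sorted(
        (l.taxon.label if l.taxon else l.label or "") for l in leaves
    )
    if any(not lab for lab in labels):
        raise ValidationError("every tip must carry a label")
    tip_idx = {lab: i for i, lab in enumerate(labels)}
    n_tips = len(labels)
    index = {}
    next_internal = n_tips
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            index[nd] = tip_idx[nd.taxon.label if nd.taxon else nd.label]
        else:
            index[nd] = next_internal
            next_internal += 1
    n = next_internal
    parent = np.full(n, -1, dtype=int)
    age = np.zeros(n)
    children = {}
    for nd in tree.preorder_node_iter():
        i = index[nd]
        age[i] = maxd - depth[nd]
        if nd.parent_node is not None:
            parent[i] = index[nd.parent_node]
        if not nd.is_leaf():
            a, b = nd.child_nodes()
            children[i] = (index[a], index[b])
    # snap tip ages to exactly zero once inside tolerance, so arithmetic
    # downstream never sees -1e-12 Ma
    tips = age[:n_tips]
    if np.all(np.abs(tips) <= ULTRAMETRIC_TOL):
        age[:n_tips] = 0.0
    return TimeTree(parent, age, children, labels)


def read_tree(path, *, stretch_tips: bool = False,
              resolve_polytomies: bool = False) -> TimeTree:
    """Read a Newick file with branch lengths in Ma into a TimeTree.

    Parameters
    ----------
    stretch_tips : extend terminal branches to the maximum root-to-tip
        depth before the ultrametricity check (absorbs dating jitter).
    resolve_polytomies : arbitrarily resolve multifurcations with 1e-9 Ma
        internal branches instead of refusing the tree.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return _timetree_from_dendropy(tree, stretch_tips, resolve_polytomies)


def tree_from_newick(newick: str, **kw) -> TimeTree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return _timetree_from_dendropy(tree, kw.get("stretch_tips", False),
                                   kw.get("resolve_polytomies", False))


def tree_to_newick(tree: TimeTree) -> str:
    """Serialise a TimeTree back to Newick (12 significant digits)."""

    def fmt(x):
        return format(x, ".12g")

    def rec(i):
        if i < tree.n_tips:
            return tree.labels[i]
        a, b = tree.children[i]
        la = tree.age[i] - tree.age[a]
        lb = tree.age[i] - tree.age[b]
        return f"({rec(a)}:{fmt(la)},{rec(b)}:{fmt(lb)})"

    return rec(tree.root) + ";"


def write_tree(tree: TimeTree, path) -> None:
    pathlib.Path(path).write_text(tree_to_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# climate


def read_climate(path, kind: str = "d18O") -> ClimateSeries:
    """Read a climate CSV (columns ``age_ma,value``) into a ClimateSeries.

    Rows are sorted ascending in age; duplicate ages are averaged.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if "age_ma" in cols and "value" in cols:
        df.columns = cols
        age, val = df["age_ma"], df["value"]
    elif df.shape[1] >= 2:
        age, val = df.iloc[:, 0], df.iloc[:, 1]
    else:
        raise ValidationError("climate CSV needs columns age_ma,value")
    age = pd.to_numeric(age, errors="raise")
    val = pd.to_numeric(val, errors="raise")
    if age.isna().any() or val.isna().any():
        raise ValidationError("missing values in climate CSV")
    g = pd.DataFrame({"age": age, "value": val}).groupby("age", sort=True)
    agg = g.mean().reset_index()
    return ClimateSeries(agg["age"].to_numpy(), agg["value"].to_numpy(),
                         kind=kind, provenance={"source": str(path)})


def write_climate(series: ClimateSeries, path) -> None:
    pd.DataFrame({"age_ma": series.age, "value": series.value}).to_csv(
        path, index=False
    )
    side = pathlib.Path(str(path) + ".provenance.json")
    side.write_text(json.dumps(
        {"kind": series.kind, "window": series.window,
         **series.provenance}, indent=2, default=str))


# ---------------------------------------------------------------------------
# geography


def read_geography(path, ceiling: float = np.inf) -> GeographyModel:
    """Read a geography YAML/JSON: areas, distance_km matrix, emergence_ma."""
    text = pathlib.Path(path).read_text()
    doc = yaml.safe_load(text)
    areas = list(doc["areas"])
    dist = np.asarray(doc["distance_km"], dtype=float)
    emer_map = doc.get("emergence_ma", {}) or {}
    emer = np.array([float(emer_map.get(a, np.inf)) for a in areas])
    return GeographyModel(areas, dist, emer, ceiling=ceiling)


def write_geography(geo: GeographyModel, path) -> None:
    doc = {
        "areas": list(geo.areas),
        "distance_km": geo.distance_km.tolist(),
        "emergence_ma": {
            a: float(e)
            for a, e in zip(geo.areas, geo.emergence_age)
            if np.isfinite(e)
        },
    }
    pathlib.Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_ranges(path) -> dict:
    """Tip range TSV (tip_label, semicolon-joined area codes) -> dict."""
    out = {}
    for line in pathlib.Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, ranges = line.split("\t")
        out[label] = tuple(a for a in ranges.split(";") if a)
        if not out[label]:
            raise ValidationError(f"empty range for tip {label!r}")
    return out


def write_ranges(tip_ranges: dict, path) -> None:
    lines = [f"{k}\t{';'.join(v)}" for k, v in tip_ranges.items()]
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, format: str = "matrix_csv",
                   pop_map=None) -> GenotypeMatrix:
    """Read genotypes from a matrix CSV or a VCF.

    matrix CSV layout: columns ``id``, ``pop``, then one column per locus,
    entries in {0,1,2,NA} (alternate-allele counts).  VCF: biallelic SNP
    records only; multi-allelic records are dropped with a logged count;
    ``pop_map`` (dict or TSV path of ``sample<TAB>pop``) supplies labels.
    """
    if format == "matrix_csv":
        return _read_genotype_csv(path)
    if format == "vcf":
        return _read_genotype_vcf(path, pop_map)
    raise ValidationError(f"unknown genotype format {format!r}")


def _read_genotype_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str)
    if "id" not in df.columns or "pop" not in df.columns:
        raise ValidationError("genotype CSV needs 'id' and 'pop' columns")
    loci = [c for c in df.columns if c not in ("id", "pop")]
    ids = df["id"].tolist()
    pops = df["pop"].tolist()
    if any(pd.isna(p) or str(p) == "" for p in pops):
        raise ValidationError("individual without population label")
    geno = np.full((len(ids), len(loci)), MISSING, dtype=np.int8)
    for j, locus in enumerate(loci):
        col = df[locus]
        for i, raw in enumerate(col):
            if pd.isna(raw) or str(raw).upper() in ("NA", ""):
                continue
            try:
                v = int(raw)
            except ValueError:
                v = -9
            if v not in (0, 1, 2):
                raise ValidationError(
                    f"invalid genotype code {raw!r} for individual "
                    f"{ids[i]!r} at locus {locus!r}"
                )
            geno[i, j] = v
    return GenotypeMatrix(ids, pops, loci, geno)


def _read_genotype_vcf(path, pop_map) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if pop_map is None:
        raise ValidationError("VCF input requires a pop_map")
    if not isinstance(pop_map, dict):
        pop_map = {
            line.split("\t")[0]: line.split("\t")[1].strip()
            for line in pathlib.Path(pop_map).read_text().splitlines()
            if line.strip()
        }
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing_pops = [s for s in samples if s not in pop_map]
    if missing_pops:
        raise ValidationError(
            f"individuals without population label: {missing_pops}")
    rows, loci = [], []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_dropped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.array(var.gt_types)
        row = np.full(len(samples), MISSING, dtype=np.int8)
        row[gt == 0] = 0
        row[gt == 1] = 1
        row[gt == 3] = 2
        rows.append(row)
        loci.append(var.ID or f"{var.CHROM}:{var.POS}")
    if n_dropped:
        log.info("dropped %d multi-allelic VCF records", n_dropped)
    geno = (np.array(rows, dtype=np.int8).T if rows
            else np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples, [pop_map[s] for s in samples], loci, geno)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    data = {"id": gm.ids, "pop": gm.pops}
    g = gm.genotype.astype(object)
    g[g == MISSING] = "NA"
    for j, locus in enumerate(gm.loci):
        data[str(locus)] = g[:, j]
    pd.DataFrame(data).to_csv(path, index=False)
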