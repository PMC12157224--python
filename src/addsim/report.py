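"""Pipeline orchestration and tabular emitters.

Runs the full additive-profiling workflow — census, descriptors,
similarity matrices, hierarchical clustering with validation and
bootstrap stability, risk flags — from a single flat-text config, and
writes every result as TSV/JSON plus a manifest.  All outputs are
re-parseable by the package's own readers, and a fixed config + seed
yields byte-identical JSON outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as cl
from . import descriptors as de
from . import riskflags as rf
from . import similarity as si
from .molgraph import Molecule, ParseError, parse_sdf, parse_smiles

__all__ = [
    "PipelineConfig",
    "read_molecules",
    "run_pipeline",
    "cluster_property_summary",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

log = logging.getLogger("addsim")


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable pipeline configuration."""
    input: str = ""
    method: str = "mcs"              # ap | mcs
    distance: str = "oc"             # oc | tc (mcs) — ap uses Eq-1 TC
    cutoff: float = 0.30
    atom_mismatches: int = 0
    bond_mismatches: int = 0
    timeout: float = 10.0            # seconds per MCS pair
    linkage: str = "ward.d2"
    k_min: int = 2
    k_max: int = 6
    bootstrap: int = 100
    seed: int = 42
    outdir: str = "addsim_out"

    def validate(self) -> None:
        if self.method not in ("ap", "mcs"):
            raise ValueError(f"method must be ap|mcs, got {self.method!r}")
        if self.distance not in ("oc", "tc"):
            raise ValueError(f"distance must be oc|tc, got {self.distance!r}")
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("cutoff must lie in [0, 1]")
        if self.linkage not in cl.LINKAGES:
            raise ValueError(f"linkage must be one of {cl.LINKAGES}")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.bootstrap < 1:
            raise ValueError("bootstrap count must be positive")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)


def read_molecules(path: str | Path) -> list[Molecule]:
    """Read molecules from an SDF (.sdf) or SMILES table.

    SMILES files carry one molecule per line: SMILES, optionally followed
    by a tab-separated id; a header line starting with 'smiles' or 'cid'
    is skipped.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".sdf":
        return parse_sdf(text)
    mols = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"no molecules in {path}")
    header = lines[0].lower().split("\t")
    if "smiles" in header or "cid" in header:
        rows = [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]
        for row in rows:
            cid = row.get("cid")
            mols.append(parse_smiles(
                row["smiles"],
                cid=int(cid) if cid and cid.isdigit() else None,
                name=row.get("name")))
    else:
        for ln in lines:
            parts = ln.split("\t")
            cid = (int(parts[1]) if len(parts) > 1 and parts[1].isdigit()
                   else None)
            mols.append(parse_smiles(parts[0], cid=cid))
    return mols


# ---------------------------------------------------------------------------
# Matrix emitters
# ---------------------------------------------------------------------------

def write_matrix_tsv(sm: si.SimilarityMatrix, path: str | Path,
                     masked: bool = True) -> None:
    """Upper-triangle TSV; cells below the cutoff are left blank."""
    vals = sm.masked() if masked else sm.values
    n = len(sm.ids)
    with open(path, "w") as fh:
        fh.write("CID\t" + "\t".join(str(i) for i in sm.ids) + "\n")
        for i in range(n):
            cells = []
            for j in range(n):
                if j < i:
                    cells.append("")
                else:
                    v = vals[i, j]
                    cells.append("" if np.isnan(v) else f"{v:.2f}")
            fh.write(f"{sm.ids[i]}\t" + "\t".join(cells) + "\n")


def read_matrix_tsv(path: str | Path) -> si.SimilarityMatrix:
    """Read an upper-triangle TSV back into a symmetric matrix."""
    lines = Path(path).read_text().splitlines()
    ids = [_maybe_int(x) for x in lines[0].split("\t")[1:]]
    n = len(ids)
    v = np.full((n, n), np.nan)
    for i, ln in enumerate(lines[1:]):
        for j, cell in enumerate(ln.split("\t")[1:]):
            if cell:
                v[i, j] = v[j, i] = float(cell)
    return si.SimilarityMatrix(ids=ids, values=v)


def _maybe_int(x: str):
    return int(x) if x.isdigit() else x


def _matrix_json(sm: si.SimilarityMatrix) -> dict:
    return {"ids": [int(i) if isinstance(i, (int, np.integer)) else i
                    for i in sm.ids],
            "values": [[round(float(x), 12) for x in row]
                       for row in sm.values]}


# ---------------------------------------------------------------------------
# Cluster property summary
# ---------------------------------------------------------------------------

def cluster_property_summary(labels: dict, properties: pd.DataFrame,
                             ) -> pd.DataFrame:
    """Per-cluster min/max/mean/sample-sd for each property column.

    ``labels`` maps id → cluster; ``properties`` is indexed by the same
    ids.  Single-member clusters report their value as min = max = mean
    and no standard deviation.
    """
    missing = set(labels) - set(properties.index)
    if missing:
        raise ValueError(f"ids without property rows: {sorted(missing)}")
    rows = []
    for cluster in sorted(set(labels.values())):
        members = [i for i, c in labels.items() if c == cluster]
        sub = properties.loc[members]
        for col in properties.columns:
            x = sub[col].astype(float)
            rows.append({
                "cluster": cluster, "property": col, "n": len(x),
                "min": x.min(), "max": x.max(), "mean": x.mean(),
                "sd": x.std(ddof=1) if len(x) > 1 else np.nan,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.monotonic()
            out = fn(*args, **kwargs)
            log.info("%s finished in %.2fs", name, time.monotonic() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run census → descriptors → similarity → clustering → risk.

    Writes every artifact under ``config.outdir`` with a manifest; the
    returned bundle holds the in-memory objects.  Raises ParseError for
    unreadable input, ValueError for bad configuration.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mols = read_molecules(config.input)
    if not mols:
        raise ParseError("empty input")
    log.info("parsed %d molecules from %s", len(mols), config.input)

    desc = de.descriptor_table(mols)
    desc_out = desc.copy()
    desc_out[["logp", "mr", "tpsa"]] = desc_out[["logp", "mr", "tpsa"]].round(
        {"logp": 4, "mr": 4, "tpsa": 2})
    desc_out.to_csv(outdir / "descriptors.tsv", sep="\t", index=False)

    ap = si.ap_matrix(mols, cutoff=config.cutoff)
    write_matrix_tsv(ap, outdir / "ap_similarity.tsv")
    files = ["descriptors.tsv", "ap_similarity.tsv"]

    bundle: dict = {"molecules": mols, "descriptors": desc, "ap": ap}
    if config.method == "mcs":
        ocm, tcm, done = si.mcs_matrix(
            mols, config.atom_mismatches, config.bond_mismatches,
            timeout=config.timeout, cutoff=config.cutoff)
        write_matrix_tsv(ocm, outdir / "mcs_oc.tsv", masked=False)
        write_matrix_tsv(tcm, outdir / "mcs_tc.tsv", masked=False)
        files += ["mcs_oc.tsv", "mcs_tc.tsv"]
        log.info("mcs matrix: %d/%d pairs exhausted",
                 int(done.sum() - len(mols)) // 2,
                 len(mols) * (len(mols) - 1) // 2)
        sim = ocm if config.distance == "oc" else tcm
        bundle.update(oc=ocm, tc=tcm, mcs_exhausted=done)
    else:
        sim = ap
    dm = cl.distance_from_similarity(sim)

    tree_scores = {lk: cl.cophenetic_corr(cl.hclust(dm, lk), dm)
                   for lk in cl.LINKAGES}
    tree = cl.hclust(dm, config.linkage)
    (outdir / "dendrogram.newick").write_text(tree.to_newick() + "\n")
    labels_by_k = {}
    for k in range(config.k_min, min(config.k_max, dm.n - 1) + 1):
        lab = cl.cut_k(tree, k)
        labels_by_k[k] = lab
        pd.DataFrame({"cid": dm.ids, "cluster": lab}).to_csv(
            outdir / f"labels_k{k}.tsv", sep="\t", index=False)
        files.append(f"labels_k{k}.tsv")
    files.append("dendrogram.newick")

    X = cl.classical_mds(dm)
    report = cl.validation_report(
        X, k_range=range(config.k_min, min(config.k_max, dm.n - 1) + 1),
        linkage=config.linkage, seed=config.seed)
    report.to_csv(outdir / "validation.tsv", sep="\t", index=False)
    files.append("validation.tsv")
    k_candidates = sorted(cl.select_k(report))

    boot_rows = []
    for k in k_candidates:
        rep = cl.bootstrap_stability(dm, k, b=config.bootstrap,
                                     seed=config.seed,
                                     linkage=config.linkage)
        for ci, (aj, dr, lab) in enumerate(zip(
                rep.avg_jaccard, rep.dissolution_rate, rep.stability_label)):
            boot_rows.append({"k": k, "cluster": ci, "avg_jaccard": aj,
                              "dissolution_rate": dr, "stability": lab})
    boot = pd.DataFrame(boot_rows)
    boot.to_csv(outdir / "bootstrap.tsv", sep="\t", index=False)
    files.append("bootstrap.tsv")

    risk = pd.DataFrame([asdict(rf.assess(row.cid, row.logp, row.tpsa))
                         for row in desc.itertuples()])
    risk.to_csv(outdir / "risk.tsv", sep="\t", index=False)
    files.append("risk.tsv")

    # heatmap: distance matrix ordered by dendrogram leaves
    order = [dm.ids.index(i) for i in tree.leaf_order()]
    heat = pd.DataFrame(dm.d[np.ix_(order, order)],
                        index=[dm.ids[i] for i in order],
                        columns=[dm.ids[i] for i in order])
    heat.to_csv(outdir / "heatmap.tsv", sep="\t")
    files.append("heatmap.tsv")

    cfg_dict = asdict(config)
    cfg_dict.pop("outdir")  # results are location-independent
    result_json = {
        "config": cfg_dict,
        "n_molecules": len(mols),
        "cophenetic": {k: round(v, 12) for k, v in tree_scores.items()},
        "k_candidates": k_candidates,
        "labels": {str(k): [int(x) for x in v]
                   for k, v in labels_by_k.items()},
        "similarity": _matrix_json(sim),
        "bootstrap": boot.to_dict(orient="records"),
    }
    (outdir / "results.json").write_text(
        json.dumps(result_json, indent=1, sort_keys=True) + "\n")
    files.append("results.json")

    manifest = {"files": sorted(files), "config": asdict(config)}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")

    bundle.update(distance=dm, tree=tree, cophenetic=tree_scores,
                  labels_by_k=labels_by_k, validation=report,
                  k_candidates=k_candidates, bootstrap=boot, risk=risk)
    return bundle
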