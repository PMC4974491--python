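"""Readers and writers for the pipeline's on-disk formats.

Matrices travel as TSV with probes in rows and design-encoding sample ids
(``condition_t{hours}_d{donor}``) in columns.  Gene-set collections use GMT,
ontologies minimal OBO (id, name, is_a, relationship: part_of), annotations
GAF 2.2 (unused columns filled with ``NA``), and networks plain TSV edge
lists or GEXF with module color and betweenness as node attributes.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import ExpressionMatrix, GroundTruth, ModulePartition

# ---------------------------------------------------------------------------
# expression / detection / truth / partition TSV
# ---------------------------------------------------------------------------

def write_expression(x: ExpressionMatrix, path) -> None:
    x.values.to_csv(path, sep="\t")


def read_expression(path) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values)


def write_detection(detection: pd.DataFrame, path) -> None:
    detection.to_csv(path, sep="\t")


def read_detection(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.labels.rename("module").to_frame().to_csv(path, sep="\t")


def read_ground_truth_labels(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0)["module"]


def write_partition(part: ModulePartition, path) -> None:
    df = part.labels.rename("module").to_frame()
    df["color"] = [part.colors.get(l, l) for l in part.labels]
    if part.kwithin is not None:
        df["kWithin"] = part.kwithin
    df.to_csv(path, sep="\t")


def read_partition(path) -> ModulePartition:
    df = pd.read_csv(path, sep="\t", index_col=0)
    kw = df["kWithin"] if "kWithin" in df.columns else None
    return ModulePartition(df["module"], kw)


def write_de_result(de, path) -> None:
    df = de.table.copy()
    df["contrast"] = f"{de.contrast[0]}_vs_{de.contrast[1]}"
    df["timepoint"] = de.timepoint
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def write_gmt(signatures: dict[str, list[str]], path, description: str = "ascnet") -> None:
    with open(path, "w") as fh:
        for name, members in signatures.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file (name, description, tab-separated members).

    Empty set lines are skipped with a warning; duplicate names get a
    deterministic ``.2``, ``.3``, ... suffix; duplicated members within one
    line are deduplicated preserving order.
    """
    sigs: dict[str, list[str]] = {}
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            name, members = fields[0], [g for g in fields[2:] if g]
            if not members:
                warnings.warn(f"{path}:{lineno}: empty gene set {name!r} skipped", stacklevel=2)
                continue
            seen[name] = seen.get(name, 0) + 1
            if seen[name] > 1:
                name = f"{name}.{seen[name]}"
            sigs[name] = list(dict.fromkeys(members))
    return sigs


# ---------------------------------------------------------------------------
# OBO / GAF
# ---------------------------------------------------------------------------

def write_obo(onto: nx.MultiDiGraph, path, ontology_name: str = "toy-ontology") -> None:
    """Minimal OBO serialization (id, name, is_a, relationship: part_of)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {ontology_name}\n")
        for term in sorted(onto.nodes):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            name = onto.nodes[term].get("name", term)
            fh.write(f"name: {name}\n")
            for _, parent, key in sorted(onto.out_edges(term, keys=True)):
                if key == "is_a":
                    fh.write(f"is_a: {parent} ! {onto.nodes[parent].get('name', parent)}\n")
                else:
                    fh.write(f"relationship: {key} {parent}\n")


def read_obo(path) -> nx.MultiDiGraph:
    """Read an OBO file into an obonet-style child->parent multigraph."""
    import obonet

    return obonet.read_obo(path)


GAF_COLUMNS = 17


def write_gaf(annotations: pd.DataFrame, path, db: str = "ascnet") -> None:
    """Write gene->term annotations as GAF 2.2 rows (unused columns ``NA``)."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene, term in annotations[["gene", "term"]].itertuples(index=False):
            row = ["NA"] * GAF_COLUMNS
            row[0] = db          # DB
            row[1] = gene        # DB object id
            row[2] = gene        # DB object symbol
            row[3] = "involved_in"
            row[4] = term        # GO id
            row[6] = "IEA"       # evidence code
            row[8] = "P"         # aspect
            fh.write("\t".join(row) + "\n")


def read_gaf(path) -> pd.DataFrame:
    """Read a GAF 2.x file back into a (gene, term) table."""
    from Bio.UniProt.GOA import gafiterator

    rows = []
    with open(path) as fh:
        for rec in gafiterator(fh):
            rows.append((rec["DB_Object_ID"], rec["GO_ID"]))
    return pd.DataFrame(rows, columns=["gene", "term"])


# ---------------------------------------------------------------------------
# edges / GEXF
# ---------------------------------------------------------------------------

def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gexf(
    edges: pd.DataFrame,
    part: ModulePartition,
    betweenness: pd.Series,
    path,
) -> None:
    """GEXF export with ``module_color`` and ``betweenness`` node attributes."""
    g = nx.from_pandas_edgelist(edges, "source", "target", edge_attr="weight")
    for node in g.nodes:
        g.nodes[node]["module_color"] = str(part.labels.get(node, "grey"))
        g.nodes[node]["betweenness"] = float(betweenness.get(node, 0.0))
    nx.write_gexf(g, path)


def write_overlap(overlap, counts_path, pvals_path) -> None:
    """Overlap heat-map tables: counts and -log10 p."""
    overlap.counts.to_csv(counts_path, sep="\t")
    overlap.neglog10_p.to_csv(pvals_path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
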