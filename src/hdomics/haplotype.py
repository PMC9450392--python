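"""HTT haplotype construction, frequency-based naming, and clustering.

Haplotypes over the 21 HTT-region defining variants (20 SNPs and the
rs149109767 indel) are constructed from phased chromosomes, counted, and
named: allele vectors matching one of the reserved definitions (hap.1 ..
hap.16 in the published nomenclature) keep their reserved name regardless
of frequency; the remaining vectors are sorted by descending panel
frequency and assigned the next names (hap.17, hap.18, ...). Alleles are
encoded 0 = reference, 1 = alternate, so the "binary distance" between two
haplotypes is the Jaccard-style asymmetric distance: disagreements over
the union of alternate-allele loci. Dendrograms use Ward's linkage on that
distance; flat clusters come from k-means (k = 3 by default) on the
binary vectors, run separately for normal and mutant haplotypes when
requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

N_LOCI_DEFAULT = 21


@dataclass
class HaplotypePanel:
    """Phased chromosomes over an ordered set of variant loci.

    ``chromosomes`` is (n_chromosomes, n_loci) with entries 0 (reference),
    1 (alternate) or -1 (missing call). ``phase_index`` is 1 or 2 within
    each sample; ``mutant_flag`` (optional) marks chromosomes carrying the
    expanded CAG tract.
    """

    loci: tuple
    chromosomes: np.ndarray
    sample_ids: list
    phase_index: np.ndarray
    mutant_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chromosomes = np.asarray(self.chromosomes, dtype=np.int8)
        if self.chromosomes.ndim != 2 or self.chromosomes.shape[1] != len(self.loci):
            raise ValueError("chromosomes must be (n, n_loci) matching loci")
        if len(self.sample_ids) != len(self.chromosomes):
            raise ValueError("one sample_id per chromosome required")
        pairs = list(zip(self.sample_ids, np.asarray(self.phase_index).tolist()))
        if len(set(pairs)) != len(pairs):
            raise ValueError("phase_index must be unique within each sample")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)


@dataclass
class HaplotypeDefinition:
    name: str
    alleles: tuple
    frequency: float = 0.0

    def __post_init__(self) -> None:
        self.alleles = tuple(int(a) for a in self.alleles)
        if any(a not in (0, 1) for a in self.alleles):
            raise ValueError("alleles must be 0 (reference) or 1 (alternate)")


def construct_haplotypes(panel: HaplotypePanel) -> pd.DataFrame:
    """Count distinct allele vectors among the panel's chromosomes.

    Chromosomes with any missing call are dropped (haplotype identity
    requires all loci) and reported in the log. Returns a DataFrame with
    columns ``alleles`` (tuple), ``count`` and ``frequency`` sorted by
    descending count, frequencies relative to the retained chromosomes.
    """
    if panel.n_chromosomes == 0:
        raise ValueError("empty panel")
    complete = ~(panel.chromosomes < 0).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("construct_haplotypes: dropped %d chromosomes with "
                    "missing calls", dropped)
    chroms = panel.chromosomes[complete]
    if len(chroms) == 0:
        raise ValueError("no complete chromosomes in panel")
    vectors, counts = np.unique(chroms, axis=0, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    rows = [{"alleles": tuple(int(a) for a in vectors[i]),
             "count": int(counts[i]),
             "frequency": counts[i] / len(chroms)} for i in order]
    return pd.DataFrame(rows)


def name_haplotypes(table: pd.DataFrame,
                    reserved: list[HaplotypeDefinition]) -> list[HaplotypeDefinition]:
    """Assign names to constructed haplotypes.

    Vectors matching a reserved definition keep that reserved name
    regardless of their panel frequency. The remaining (novel) vectors are
    sorted by descending frequency — ties broken lexicographically on the
    allele string — and named hap.<r+1>, hap.<r+2>, ... continuing after
    the r reserved names. Reserved haplotypes absent from the panel are
    omitted from the output (and logged).
    """
    by_vector = {}
    for d in reserved:
        if d.alleles in by_vector:
            raise ValueError(f"duplicate reserved vector for {d.name!r} and "
                             f"{by_vector[d.alleles].name!r}")
        by_vector[d.alleles] = d
    out: list[HaplotypeDefinition] = []
    novel = []
    for _, row in table.iterrows():
        vec = tuple(row["alleles"])
        if vec in by_vector:
            out.append(HaplotypeDefinition(name=by_vector[vec].name, alleles=vec,
                                           frequency=float(row["frequency"])))
        else:
            novel.append((vec, float(row["frequency"])))
    absent = [d.name for d in reserved
              if d.alleles not in {tuple(r["alleles"]) for _, r in table.iterrows()}]
    if absent:
        logger.info("reserved haplotypes absent from panel: %s", absent)
    novel.sort(key=lambda t: (-t[1], "".join(map(str, t[0]))))
    next_number = len(reserved) + 1
    for vec, freq in novel:
        out.append(HaplotypeDefinition(name=f"hap.{next_number}", alleles=vec,
                                       frequency=freq))
        next_number += 1
    return out


def assign_diplotypes(panel: HaplotypePanel,
                      definitions: list[HaplotypeDefinition]) -> pd.DataFrame:
    """Map each sample's phased chromosome pair to named haplotypes.

    A chromosome matches a definition only exactly; non-matching
    chromosomes are "unassigned". A sample is conclusive iff both phases
    are assigned. Returns one row per sample with columns ``hap1``,
    ``hap2``, ``conclusive``.
    """
    if not definitions:
        raise ValueError("no haplotype definitions supplied")
    lut = {d.alleles: d.name for d in definitions}
    n_loci = len(panel.loci)
    per_sample: dict = {}
    for sid, phase, chrom in zip(panel.sample_ids, panel.phase_index,
                                 panel.chromosomes):
        if len(chrom) != n_loci:
            raise ValueError("allele vector of wrong length")
        if (chrom < 0).any():
            name = "unassigned"
        else:
            name = lut.get(tuple(int(a) for a in chrom), "unassigned")
        per_sample.setdefault(sid, {})[int(phase)] = name
    rows = []
    for sid, phases in per_sample.items():
        h1 = phases.get(1, "unassigned")
        h2 = phases.get(2, "unassigned")
        rows.append({"sample_id": sid, "hap1": h1, "hap2": h2,
                     "conclusive": h1 != "unassigned" and h2 != "unassigned"})
    return pd.DataFrame(rows)


def binary_distance_matrix(definitions: list[HaplotypeDefinition]) -> pd.DataFrame:
    """Pairwise binary (Jaccard-style) distance between haplotypes.

    d(a, b) = (# loci where exactly one of a, b carries the alternate) /
    (# loci where at least one does); 0 when both vectors are all-reference.
    """
    if len(definitions) < 2:
        raise ValueError("need at least two definitions")
    mat = np.array([d.alleles for d in definitions], dtype=bool)
    dist = squareform(pdist(mat, metric="jaccard"))
    names = [d.name for d in definitions]
    return pd.DataFrame(dist, index=names, columns=names)


@dataclass
class HaplotypeClustering:
    linkage_matrix: np.ndarray
    newick: str
    labels: pd.Series  # haplotype name -> k-means cluster id


def _to_newick(link: np.ndarray, leaf_names: list[str]) -> str:
    """Newick string from a scipy linkage matrix; branch lengths are
    merge-height differences."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(link)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0) if not node.is_leaf() \
            else max(parent_height, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        return (f"({rec(node.get_left(), node.dist)},"
                f"{rec(node.get_right(), node.dist)}):{length:.6g}")

    return f"({rec(tree.get_left(), tree.dist)},{rec(tree.get_right(), tree.dist)});"


def cluster_haplotypes(definitions: list[HaplotypeDefinition], k: int = 3,
                       mutant_partition: bool = False,
                       mutant: dict | None = None,
                       seed: int = 0) -> dict[str, HaplotypeClustering]:
    """Ward-linkage dendrogram plus k-means flat clusters.

    Hierarchical agglomeration uses Ward's linkage on the binary distance
    matrix; flat labels come from k-means (100 seeded restarts) on the 0/1
    allele vectors. With ``mutant_partition`` the normal and mutant
    haplotype sets (per the ``mutant`` name -> bool map) are clustered
    independently, mirroring separate trees for normal and disease
    chromosomes. Returns a mapping partition name -> clustering
    ("all", or "normal" / "mutant").
    """
    if mutant_partition:
        if mutant is None:
            raise ValueError("mutant_partition requires a mutant flag map")
        out = {}
        for part, keep in (("normal", False), ("mutant", True)):
            subset = [d for d in definitions if bool(mutant.get(d.name)) is keep]
            if subset:
                out[part] = _cluster_one(subset, k, seed)
        return out
    return {"all": _cluster_one(definitions, k, seed)}


def _cluster_one(definitions: list[HaplotypeDefinition], k: int,
                 seed: int) -> HaplotypeClustering:
    if k > len(definitions):
        raise ValueError(f"k={k} exceeds the {len(definitions)} definitions")
    names = [d.name for d in definitions]
    vectors = np.array([d.alleles for d in definitions], dtype=float)
    if len(definitions) >= 2:
        condensed = pdist(vectors.astype(bool), metric="jaccard")
        link = linkage(condensed, method="ward")
        newick = _to_newick(link, names)
    else:
        link = np.empty((0, 4))
        newick = f"({names[0]}:0);"
    if k == 1:
        labels = np.zeros(len(definitions), dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=100, random_state=seed)
        labels = km.fit_predict(vectors)
    return HaplotypeClustering(linkage_matrix=link, newick=newick,
                               labels=pd.Series(labels, index=names, name="cluster"))


# ---------------------------------------------------------------------------
# I/O: minimal phased VCF and TSV panels

def write_panel_vcf(panel: HaplotypePanel, path) -> None:
    """Write the panel as a minimal uncompressed phased VCF (GT "a|b").

    Loci are placed on chromosome 4 at consecutive synthetic positions;
    only sample columns with both phases present are written.
    """
    samples = sorted(set(panel.sample_ids), key=panel.sample_ids.index)
    gt = {}
    for sid, phase, chrom in zip(panel.sample_ids, panel.phase_index,
                                 panel.chromosomes):
        gt.setdefault(sid, {})[int(phase)] = chrom
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=4>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, locus in enumerate(panel.loci):
            ref, alt = ("A", "AG") if locus == "rs149109767" else ("A", "G")
            fields = ["4", str(3_070_000 + j * 1000), str(locus), ref, alt,
                      ".", "PASS", ".", "GT"]
            for sid in samples:
                phases = gt[sid]
                a = phases.get(1)
                b = phases.get(2)
                va = "." if a is None or a[j] < 0 else str(int(a[j]))
                vb = "." if b is None or b[j] < 0 else str(int(b[j]))
                fields.append(f"{va}|{vb}")
            fh.write("\t".join(fields) + "\n")


def read_panel_vcf(path) -> HaplotypePanel:
    """Read a phased VCF (plain text, GT "a|b") into a panel."""
    loci, rows, samples = [], [], None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            parts = line.split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            loci.append(parts[2])
            calls = []
            for cell in parts[9:]:
                gtv = cell.split(":")[0]
                sep = "|" if "|" in gtv else "/"
                a, b = (gtv.split(sep) + ["."])[:2]
                calls.append((-1 if a == "." else int(a),
                              -1 if b == "." else int(b)))
            rows.append(calls)
    if samples is None:
        raise ValueError("no #CHROM header line in VCF")
    arr = np.array(rows, dtype=np.int8)  # loci x samples x 2
    sample_ids, phases, chroms = [], [], []
    for si, sid in enumerate(samples):
        for ph in (1, 2):
            sample_ids.append(sid)
            phases.append(ph)
            chroms.append(arr[:, si, ph - 1])
    return HaplotypePanel(loci=tuple(loci), chromosomes=np.array(chroms),
                          sample_ids=sample_ids,
                          phase_index=np.array(phases, dtype=np.int8))


def read_reserved_definitions(path) -> list[HaplotypeDefinition]:
    """Read reserved haplotype definitions from TSV: ``name`` column plus
    one 0/1 column per locus, in locus order."""
    df = pd.read_csv(path, sep="\t")
    allele_cols = [c for c in df.columns if c not in ("name", "frequency")]
    return [HaplotypeDefinition(name=row["name"],
                                alleles=tuple(int(row[c]) for c in allele_cols))
            for _, row in df.iterrows()]


def write_definitions(definitions: list[HaplotypeDefinition], loci, path) -> None:
    rows = []
    for d in definitions:
        row = {"name": d.name, "frequency": d.frequency}
        row.update({locus: a for locus, a in zip(loci, d.alleles)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
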