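"""Input/output: bulk VAF tables (SSM dialect), result archives, Newick.

The SSM ("simple somatic mutation") dialect is the de-facto standard of
prior subclonal-reconstruction tools: a tab-separated table with columns
``id``, ``name``, ``var_reads``, ``total_reads``, ``var_read_prob``, where
the count columns hold comma-separated per-sample lists, accompanied by a
params JSON carrying the sample names (``{"samples": [...]}``).

A sample may mark a mutation unobserved with ``total_reads = 0``; such
entries contribute nothing to any likelihood.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .phylo_model import ROOT, MutationTree

ARCHIVE_VERSION = 1

SSM_COLUMNS = ["id", "name", "var_reads", "total_reads", "var_read_prob"]


@dataclass
class VafDataset:
    """Per-mutation, per-sample bulk read counts.

    ``var_reads[j, s]`` (b) and ``ref_reads[j, s]`` (a) are the variant and
    reference read counts for mutation ``j`` in sample ``s``; ``omega`` is
    the variant read probability, the expected fraction of alleles in a
    mutated cell that carry the variant (1/2 at a diploid CNA-free locus).
    """

    mutation_ids: list[str]
    mutation_names: list[str]
    var_reads: np.ndarray
    ref_reads: np.ndarray
    omega: np.ndarray
    sample_names: list[str]

    def __post_init__(self) -> None:
        self.var_reads = np.asarray(self.var_reads, dtype=np.int64)
        self.ref_reads = np.asarray(self.ref_reads, dtype=np.int64)
        self.omega = np.asarray(self.omega, dtype=np.float64)
        shape = self.var_reads.shape
        if self.ref_reads.shape != shape or self.omega.shape != shape:
            raise ValueError("var_reads, ref_reads and omega must share shape")
        if len(self.mutation_ids) != shape[0] or len(self.sample_names) != shape[1]:
            raise ValueError("id/sample label counts do not match matrix shape")
        if (self.var_reads < 0).any() or (self.ref_reads < 0).any():
            raise ValueError("read counts must be nonnegative")
        if ((self.omega < 0) | (self.omega > 1)).any():
            raise ValueError("variant read probability must lie in [0, 1]")

    @property
    def n_mutations(self) -> int:
        return self.var_reads.shape[0]

    @property
    def n_samples(self) -> int:
        return self.var_reads.shape[1]

    @property
    def total_reads(self) -> np.ndarray:
        return self.var_reads + self.ref_reads

    def vaf(self) -> np.ndarray:
        """Observed VAF b/(a+b); zero where no reads were mapped."""
        N = self.total_reads
        with np.errstate(invalid="ignore", divide="ignore"):
            lam = np.where(N > 0, self.var_reads / np.maximum(N, 1), 0.0)
        return lam


def read_ssm(ssm_path, params_path) -> VafDataset:
    """Read an SSM table plus params JSON into a :class:`VafDataset`.

    Inconsistent rows are rejected, never repaired, and error messages name
    the offending mutation id.
    """
    df = pd.read_csv(ssm_path, sep="\t", dtype=str)
    missing = [c for c in SSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SSM file is missing required header column(s): {missing}")
    with open(params_path) as fh:
        params = json.load(fh)
    if "samples" not in params:
        raise ValueError("params JSON must contain a 'samples' list")
    samples = list(params["samples"])
    m = len(samples)

    ids, names, var_rows, tot_rows, omega_rows = [], [], [], [], []
    for _, row in df.iterrows():
        mid = str(row["id"])
        try:
            var = np.array([int(x) for x in str(row["var_reads"]).split(",")])
            tot = np.array([int(x) for x in str(row["total_reads"]).split(",")])
            omg = np.array([float(x) for x in str(row["var_read_prob"]).split(",")])
        except ValueError as exc:
            raise ValueError(f"mutation {mid}: unparsable count list: {exc}") from exc
        if not (len(var) == len(tot) == len(omg) == m):
            raise ValueError(
                f"mutation {mid}: per-sample lists have ragged lengths "
                f"({len(var)}, {len(tot)}, {len(omg)}) for {m} samples"
            )
        if (var > tot).any():
            raise ValueError(f"mutation {mid}: var_reads exceeds total_reads")
        if ((omg < 0) | (omg > 1)).any():
            raise ValueError(f"mutation {mid}: var_read_prob outside [0, 1]")
        ids.append(mid)
        names.append(str(row["name"]))
        var_rows.append(var)
        tot_rows.append(tot)
        omega_rows.append(omg)

    var = np.array(var_rows, dtype=np.int64).reshape(len(ids), m)
    tot = np.array(tot_rows, dtype=np.int64).reshape(len(ids), m)
    omg = np.array(omega_rows, dtype=np.float64).reshape(len(ids), m)
    return VafDataset(ids, names, var, tot - var, omg, samples)


def write_ssm(data: VafDataset, ssm_path, params_path) -> None:
    """Write a dataset back out in the SSM dialect."""
    rows = []
    tot = data.total_reads
    for j in range(data.n_mutations):
        rows.append(
            {
                "id": data.mutation_ids[j],
                "name": data.mutation_names[j],
                "var_reads": ",".join(str(x) for x in data.var_reads[j]),
                "total_reads": ",".join(str(x) for x in tot[j]),
                "var_read_prob": ",".join(repr(float(x)) for x in data.omega[j]),
            }
        )
    pd.DataFrame(rows, columns=SSM_COLUMNS).to_csv(ssm_path, sep="\t", index=False)
    with open(params_path, "w") as fh:
        json.dump({"samples": data.sample_names}, fh)


@dataclass
class ResultArchive:
    """Reconstruction results: distinct trees with scores and fitted matrices.

    ``parents[t]`` is the parent vector of tree ``t`` (entry ``j`` = parent
    of mutation ``j+1``, 0 = root); ``log_scores`` are the unnormalized log
    posterior scores phi; ``weights`` are the normalized posterior weights
    (softmax of phi over distinct trees); ``U``/``F`` are the fitted clonal
    proportions and tree-implied mutation frequencies, rows in input
    mutation order.
    """

    parents: np.ndarray          # (k, n) int
    log_scores: np.ndarray       # (k,)
    weights: np.ndarray          # (k,)
    U: np.ndarray                # (k, n, m)
    F: np.ndarray                # (k, n, m)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parents = np.asarray(self.parents, dtype=np.int64)
        self.log_scores = np.asarray(self.log_scores, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.U = np.asarray(self.U, dtype=np.float64)
        self.F = np.asarray(self.F, dtype=np.float64)
        if (self.weights < 0).any():
            raise ValueError("posterior weights must be nonnegative")
        if self.weights.size and abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("posterior weights must sum to 1 over distinct trees")

    @property
    def n_trees(self) -> int:
        return self.parents.shape[0]

    def trees(self) -> list[MutationTree]:
        return [MutationTree.from_parent_vector(p) for p in self.parents]

    def best_tree(self) -> MutationTree:
        return MutationTree.from_parent_vector(self.parents[int(np.argmax(self.log_scores))])


def write_results(archive: ResultArchive, path) -> None:
    """Serialize an archive: a zip of raw ``.npy`` arrays + JSON manifest."""
    manifest = {"version": ARCHIVE_VERSION, "metadata": archive.metadata}
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest))
        for name in ("parents", "log_scores", "weights", "U", "F"):
            buf = io.BytesIO()
            np.save(buf, getattr(archive, name))
            zf.writestr(name + ".npy", buf.getvalue())


def load_results(path) -> ResultArchive:
    """Load an archive written by :func:`write_results`.

    Weight vectors whose sum drifts within 1e-9 of 1 are renormalized;
    anything else, or a corrupt payload, is an error rather than a partial
    archive.
    """
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            arrays = {
                name: np.load(io.BytesIO(zf.read(name + ".npy")))
                for name in ("parents", "log_scores", "weights", "U", "F")
            }
    except (zipfile.BadZipFile, KeyError, ValueError) as exc:
        raise ValueError(f"corrupt result archive: {exc}") from exc
    if manifest.get("version") != ARCHIVE_VERSION:
        raise ValueError(
            f"result archive version {manifest.get('version')!r} "
            f"does not match expected {ARCHIVE_VERSION}"
        )
    w = arrays["weights"]
    if w.size and abs(w.sum() - 1.0) <= 1e-9:
        w = w / w.sum()
    return ResultArchive(
        arrays["parents"], arrays["log_scores"], w, arrays["U"], arrays["F"],
        metadata=manifest.get("metadata", {}),
    )


def _unique_names(names: Sequence[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}_{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def export_newick(tree: MutationTree, names: Sequence[str] | None = None) -> str:
    """Newick string for a complete tree; the root is labelled ``germline``
    and nodes carry mutation names (collisions resolved by suffixing)."""
    n = tree.node_count
    if set(tree.labels) != set(range(1, n + 1)):
        raise ValueError("newick export requires a complete tree over 1..n")
    if names is None:
        names = [f"m{j}" for j in range(1, n + 1)]
    names = _unique_names([str(x) for x in names])
    kids = tree.children_map()

    def render(v: int) -> str:
        label = "germline" if v == ROOT else names[v - 1]
        ch = kids.get(v, [])
        if not ch:
            return label
        return "(" + ",".join(render(c) for c in ch) + ")" + label

    return render(ROOT) + ";"


def parse_newick(text: str, names: Sequence[str] | None = None) -> MutationTree:
    """Parse a Newick string produced by :func:`export_newick` back into a
    tree.

    ``names`` maps node labels back to mutation indices (label ``names[j]``
    becomes mutation ``j+1``); when omitted, the exporter's default labels
    ``m1..mn`` are assumed.
    """
    import dendropy

    dtree = dendropy.Tree.get(
        data=text, schema="newick",
        suppress_internal_node_taxa=False, preserve_underscores=True,
    )

    def label_of(node) -> str:
        if node.taxon is not None and node.taxon.label is not None:
            return str(node.taxon.label)
        return str(node.label)

    labels = [label_of(nd) for nd in dtree.preorder_node_iter()]
    muts = [lab for lab in labels if lab != "germline"]
    if names is None:
        if not all(m.startswith("m") and m[1:].isdigit() for m in muts):
            raise ValueError("cannot infer mutation indices; pass the names list")
        index = {m: int(m[1:]) for m in muts}
    else:
        index = {name: j + 1 for j, name in enumerate(_unique_names([str(x) for x in names]))}
    parent = {}
    for nd in dtree.preorder_node_iter():
        lab = label_of(nd)
        if lab == "germline":
            continue
        plab = label_of(nd.parent_node)
        parent[index[lab]] = ROOT if plab == "germline" else index[plab]
    return MutationTree(parent)


def write_parent_vectors(trees: Sequence[MutationTree], path) -> None:
    """Plain-text parent vectors: one line per tree, entry ``j`` = parent of
    mutation ``j`` (0 = root)."""
    with open(path, "w") as fh:
        for t in trees:
            fh.write(" ".join(str(int(p)) for p in t.parent_vector()) + "\n")


def read_parent_vectors(path) -> list[MutationTree]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(MutationTree.from_parent_vector([int(x) for x in line.split()]))
    return out
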