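"""Plain-text file formats: edge lists, expression matrices, fitted models.

* Network edge list — TSV with columns ``regulator``, ``target``, ``kind``
  (linear / pair / drug), ``partner`` (second regulator for pairs, empty
  otherwise) and ``locked`` (0/1).  Genes are referenced by 1-based index
  or by name resolved against an expression header; drug rows use the
  1-based input index in the regulator column.
* Expression — TSV, rows are genes (first column the gene name), columns
  are time points named ``t<k>`` or ``t<k>_rep<j>`` for replicates.
* Drug series — TSV, rows are time points, one column per input.
* Fitted model — JSON carrying the structure, parameter arrays and fit
  metadata (seeds, engine, loglik).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CTMParameters, NetworkStructure, ObservationSet

__all__ = ["read_network", "write_network", "read_expression",
           "write_expression", "read_drug", "model_to_json",
           "model_from_json", "read_gene_list"]


def _resolve(token, gene_names: list[str] | None) -> int:
    s = str(token).strip()
    if gene_names is not None and s in gene_names:
        return gene_names.index(s)
    return int(s) - 1


def read_network(path, p: int | None = None,
                 gene_names: list[str] | None = None) -> NetworkStructure:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"regulator", "target", "kind"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge list needs columns {sorted(required)}")
    if p is None:
        p = len(gene_names) if gene_names else 0
        for _, row in df.iterrows():
            for tok in (row["regulator"], row["target"]):
                try:
                    p = max(p, int(tok))
                except ValueError:
                    pass
    n_drugs = 0
    structure = NetworkStructure(p=p, M=0)
    locked: set[tuple[int, int]] = set()
    drug_rows = []
    for _, row in df.iterrows():
        i = _resolve(row["target"], gene_names)
        kind = row["kind"].strip()
        if kind == "drug":
            m = int(row["regulator"]) - 1
            n_drugs = max(n_drugs, m + 1)
            drug_rows.append((i, m))
            continue
        j = _resolve(row["regulator"], gene_names)
        if kind == "linear":
            structure.linear_sets[i].add(j)
            if str(row.get("locked", "0")).strip() in {"1", "true", "True"}:
                locked.add((j, i))
        elif kind == "pair":
            k = _resolve(row["partner"], gene_names)
            j, k = min(j, k), max(j, k)
            structure.linear_sets[i].add(j)
            structure.linear_sets[i].add(k)
            structure.pair_sets[i].add((j, k))
        else:
            raise ValueError(f"unknown edge kind {kind!r}")
    structure.M = n_drugs
    for i, m in drug_rows:
        structure.drug_sets[i].add(m)
    structure.locked_edges = locked
    structure.validate()
    return structure


def write_network(structure: NetworkStructure, path,
                  gene_names: list[str] | None = None) -> None:
    def name(idx: int) -> str:
        return gene_names[idx] if gene_names else str(idx + 1)

    rows = []
    for i in range(structure.p):
        for j in sorted(structure.linear_sets[i]):
            rows.append({"regulator": name(j), "target": name(i),
                         "kind": "linear", "partner": "",
                         "locked": int((j, i) in structure.locked_edges)})
        for (j, k) in sorted(structure.pair_sets[i]):
            rows.append({"regulator": name(j), "target": name(i),
                         "kind": "pair", "partner": name(k), "locked": 0})
        for m in sorted(structure.drug_sets[i]):
            rows.append({"regulator": str(m + 1), "target": name(i),
                         "kind": "drug", "partner": "", "locked": 0})
    pd.DataFrame(rows, columns=["regulator", "target", "kind", "partner",
                                "locked"]).to_csv(path, sep="\t", index=False)


def read_expression(path, d: np.ndarray | None = None,
                    series_id: str | None = None
                    ) -> tuple[ObservationSet, list[str]]:
    """Parse a genes-by-timepoints TSV into an observation set.

    Column names ``t3`` or ``t3_rep2`` map to time 3 (1-based); times
    absent from the header are treated as unobserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene_names = [str(g) for g in df.index]
    times: dict[int, list[np.ndarray]] = {}
    for col in df.columns:
        base = col.split("_rep")[0]
        if not base.startswith("t"):
            raise ValueError(f"unrecognized time column {col!r}")
        t = int(base[1:])
        times.setdefault(t, []).append(df[col].to_numpy(dtype=float))
    T = max(times)
    y: list[np.ndarray | None] = [None] * T
    for t, reps in times.items():
        y[t - 1] = np.vstack(reps)
    obs = ObservationSet(y=y, observed_times=sorted(times), d=d,
                         series_id=series_id or Path(str(path)).stem)
    return obs, gene_names


def write_expression(obs: ObservationSet, path,
                     gene_names: list[str] | None = None) -> None:
    p = obs.p
    names = gene_names or [f"g{i + 1}" for i in range(p)]
    data: dict[str, np.ndarray] = {}
    for t in obs.observed_times:
        reps = obs.y[t - 1]
        for j, rep in enumerate(reps):
            col = f"t{t}" if reps.shape[0] == 1 else f"t{t}_rep{j + 1}"
            data[col] = rep
    pd.DataFrame(data, index=pd.Index(names, name="gene")).to_csv(path, sep="\t")


def read_drug(path) -> np.ndarray:
    """Read a time-by-inputs TSV into a (T, M) array."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float)


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


def model_to_json(structure: NetworkStructure, params: CTMParameters,
                  metadata: dict | None = None) -> str:
    payload = {
        "structure": {
            "p": structure.p,
            "M": structure.M,
            "linear_sets": [sorted(s) for s in structure.linear_sets],
            "pair_sets": [sorted(map(list, s)) for s in structure.pair_sets],
            "drug_sets": [sorted(s) for s in structure.drug_sets],
            "tf_mask": structure.tf_mask.astype(int).tolist(),
            "locked_edges": sorted(map(list, structure.locked_edges)),
        },
        "params": {
            "a": params.a.tolist(),
            "b": [[i, list(pair), v] for (i, pair), v in sorted(params.b.items())],
            "g": params.g.tolist(),
            "u": params.u.tolist(),
            "q_diag": params.q_diag.tolist(),
            "r_diag": params.r_diag.tolist(),
            "mu0": params.mu0.tolist(),
            "sigma0_diag": params.sigma0_diag.tolist(),
        },
        "metadata": metadata or {},
    }
    return json.dumps(payload, indent=1)


def model_from_json(text: str) -> tuple[NetworkStructure, CTMParameters, dict]:
    payload = json.loads(text)
    s = payload["structure"]
    structure = NetworkStructure(
        p=s["p"], M=s["M"],
        linear_sets=[set(v) for v in s["linear_sets"]],
        pair_sets=[{tuple(pr) for pr in v} for v in s["pair_sets"]],
        drug_sets=[set(v) for v in s["drug_sets"]],
        tf_mask=np.array(s["tf_mask"], dtype=bool),
        locked_edges={tuple(e) for e in s["locked_edges"]},
    )
    q = payload["params"]
    params = CTMParameters(
        a=np.array(q["a"]),
        b={(i, tuple(pair)): v for i, pair, v in q["b"]},
        g=np.array(q["g"]).reshape(s["p"], max(s["M"], 0)),
        u=np.array(q["u"]),
        q_diag=np.array(q["q_diag"]),
        r_diag=np.array(q["r_diag"]),
        mu0=np.array(q["mu0"]),
        sigma0_diag=np.array(q["sigma0_diag"]),
    )
    return structure, params, payload.get("metadata", {})
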