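"""Plain-text file formats for pedigrees, SNP genotypes, phenotypes, reports.

Pedigree files are 3 whitespace- or comma-delimited columns (animal, sire,
dam) with 0 marking an unknown parent.  SNP files follow the BLUPF90-suite
dialect: an animal id, whitespace, then a contiguous string of 0/1/2
genotype codes (5 = missing) starting at a fixed column.  Report tables are
TSV rounded to 2 decimals, with a full-precision JSON sidecar.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .simulate import UNKNOWN, Pedigree, PhenotypeSet
from .relationships import GenotypeSet

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_snp_file",
    "write_snp_file",
    "read_phenotypes",
    "write_phenotypes",
    "write_report",
    "read_stats_sidecar",
]

logger = logging.getLogger(__name__)


class FileFormatError(ValueError):
    pass


def _tokenize(line: str) -> list[str]:
    return line.replace(",", " ").split()


def _atomic_write(path: Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_pedigree(path) -> Pedigree:
    """Read and validate a 3-column pedigree file.

    The first line is skipped as a header iff its parent columns are
    non-numeric.  Animals may be listed in any order; records are
    topologically sorted so parents precede offspring.  Parents that never
    appear as animals are added as founders.  Cycles, duplicate animals and
    self-parenting raise errors with the offending line.
    """
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = _tokenize(line)
            if len(tok) < 3:
                raise FileFormatError(f"{path}:{lineno}: expected 3 columns")
            a, s, d = tok[:3]
            if lineno == 1 and not (_numeric(s) and _numeric(d)):
                continue  # header row
            if a == s or a == d:
                raise FileFormatError(
                    f"{path}:{lineno}: animal {a} listed as its own parent"
                )
            rows.append((a, s, d))

    seen: dict[str, int] = {}
    for i, (a, _, _) in enumerate(rows):
        if a in seen:
            raise FileFormatError(f"duplicate animal {a} in {path}")
        seen[a] = i

    # implicit founders for parents never listed as animals
    animals = [a for a, _, _ in rows]
    parents_only = []
    for _, s, d in rows:
        for p in (s, d):
            if p != "0" and p not in seen and p not in parents_only:
                parents_only.append(p)
    all_ids = parents_only + animals
    sire_of = {a: s for a, s, d in rows}
    dam_of = {a: d for a, s, d in rows}

    # Kahn topological sort (parents first)
    children: dict[str, list[str]] = {a: [] for a in all_ids}
    indeg = {a: 0 for a in all_ids}
    for a in animals:
        for p in (sire_of[a], dam_of[a]):
            if p != "0":
                children[p].append(a)
                indeg[a] += 1
    queue = [a for a in all_ids if indeg[a] == 0]
    order: list[str] = []
    while queue:
        a = queue.pop(0)
        order.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != len(all_ids):
        stuck = next(a for a in all_ids if indeg[a] > 0)
        raise FileFormatError(f"pedigree cycle detected involving animal {stuck}")

    pos = {a: i for i, a in enumerate(order)}

    def parent_idx(a: str, which: dict) -> int:
        if a in sire_of:
            p = which[a]
            return pos[p] if p != "0" else UNKNOWN
        return UNKNOWN

    ids = np.array([_maybe_int(a) for a in order], dtype=object)
    sire = np.array([parent_idx(a, sire_of) for a in order])
    dam = np.array([parent_idx(a, dam_of) for a in order])
    gen = np.zeros(len(order), dtype=np.int64)
    for i in range(len(order)):
        g = 0
        for p in (sire[i], dam[i]):
            if p != UNKNOWN:
                g = max(g, gen[p] + 1)
        gen[i] = g
    return Pedigree(ids=ids, sire=sire, dam=dam, generation=gen)


def _numeric(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _maybe_int(s: str):
    try:
        return int(s)
    except ValueError:
        return s


def write_pedigree(pedigree: Pedigree, path) -> None:
    lines = []
    for i in range(pedigree.n_animals):
        s = pedigree.ids[pedigree.sire[i]] if pedigree.sire[i] != UNKNOWN else 0
        d = pedigree.ids[pedigree.dam[i]] if pedigree.dam[i] != UNKNOWN else 0
        lines.append(f"{pedigree.ids[i]} {s} {d}")
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def write_snp_file(genotypes: GenotypeSet, path) -> None:
    """BLUPF90-style SNP file: padded id, one space, contiguous 0/1/2 string."""
    Z = np.asarray(genotypes.Z)
    if not np.all(np.isin(Z, [0, 1, 2])):
        raise ValueError("can only write integer 0/1/2 gene contents")
    width = max(len(str(a)) for a in genotypes.ids)
    lines = [
        f"{str(a):<{width}} " + "".join(str(int(g)) for g in row)
        for a, row in zip(genotypes.ids, Z)
    ]
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def read_snp_file(path) -> GenotypeSet:
    """Read a BLUPF90-style SNP file; 5 (missing) is imputed to 2*p-hat."""
    ids, strings = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tok = line.split()
            if len(tok) != 2:
                raise FileFormatError(f"{path}:{lineno}: expected 'id genotypes'")
            a, s = tok
            if set(s) - set("0125"):
                raise FileFormatError(
                    f"{path}:{lineno}: genotype characters must be 0/1/2/5"
                )
            ids.append(_maybe_int(a))
            strings.append(s)
    if not ids:
        raise FileFormatError(f"{path}: empty SNP file")
    lengths = {len(s) for s in strings}
    if len(lengths) != 1:
        raise FileFormatError(f"{path}: ragged genotype strings {sorted(lengths)}")
    Z = np.array([[int(c) for c in s] for s in strings], dtype=np.float64)
    missing = Z == 5
    if missing.any():
        n_missing = int(missing.sum())
        observed = ~missing
        counts = observed.sum(axis=0)
        sums = np.where(missing, 0.0, Z).sum(axis=0)
        # all-missing locus falls back to gene content 1 (p-hat = 0.5)
        col_mean = np.where(counts > 0, sums / np.maximum(counts, 1), 1.0)
        Z = np.where(missing, col_mean[None, :], Z)
        logger.info("imputed %d missing genotypes to 2*p-hat", n_missing)
    return GenotypeSet(ids=np.array(ids, dtype=object), Z=Z)


def write_phenotypes(phenotypes: PhenotypeSet, path) -> None:
    lines = [f"{a} {v:.10g}" for a, v in phenotypes.records.items()]
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def read_phenotypes(path) -> PhenotypeSet:
    """Whitespace-delimited (animal, value) records; mode inferred from codes."""
    ids, vals = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = _tokenize(line)
            if len(tok) < 2:
                raise FileFormatError(f"{path}:{lineno}: expected 'id value'")
            if lineno == 1 and not _numeric(tok[1]):
                continue
            ids.append(_maybe_int(tok[0]))
            vals.append(float(tok[1]))
    rec = pd.Series(vals, index=np.array(ids, dtype=object))
    mode = "binary_1_2" if set(np.unique(vals)) <= {1.0, 2.0} else "continuous"
    return PhenotypeSet(
        records=rec,
        true_breeding_value=pd.Series(dtype=float),
        fixed_level=pd.Series(0, index=rec.index),
        trait_mode=mode,
    )


_TABLE_COLS = ["scenario", "group", "n", "correlation", "intercept", "slope", "MD"]


def write_report(report, output_dir) -> dict:
    """Write an :class:`~apyrel.experiment.ExperimentReport` to text files.

    Produces per-comparison TSV tables (2-decimal formatting), full-precision
    JSON sidecars, fidelity/ratio/strata tables, a YAML metadata echo of the
    configuration and seeds, and a short log.  Writes are atomic
    (temp-then-rename).  Returns the mapping of artifact name -> path.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def fmt(x):
        return "" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.2f}"

    for comparison, sub in report.stats.groupby("comparison"):
        rows = ["\t".join(_TABLE_COLS)]
        # scenario labels carry per-replicate core sizes; aggregate over the
        # schedule position so replicate means line up
        key = "position" if "position" in sub.columns else "scenario"
        agg = (
            sub.groupby([key, "group"], sort=False)[
                ["n", "correlation", "intercept", "slope", "MD"]
            ]
            .mean(numeric_only=True)
            .reset_index()
        )
        if key == "position":
            label = sub.groupby("position")["scenario"].first()
            agg["scenario"] = agg["position"].map(label)
        for _, r in agg.iterrows():
            rows.append(
                "\t".join(
                    [
                        str(r["scenario"]),
                        str(r["group"]),
                        str(int(r["n"])),
                        fmt(r["correlation"]),
                        fmt(r["intercept"]),
                        fmt(r["slope"]),
                        fmt(r["MD"]),
                    ]
                )
            )
        p = out / f"table_{comparison}.tsv"
        _atomic_write(p, "\n".join(rows) + "\n")
        written[f"table_{comparison}"] = p

    sidecar = out / "stats.json"
    _atomic_write(sidecar, report.stats.to_json(orient="records", indent=1))
    written["stats_sidecar"] = sidecar

    for name, df in (
        ("fidelity", report.fidelity),
        ("ratios", report.ratios),
        ("strata", report.strata),
    ):
        p = out / f"{name}.tsv"
        _atomic_write(p, df.to_csv(sep="\t", index=False))
        written[name] = p

    import apyrel

    meta = {
        "config": report.config_echo,
        "seeds": list(report.seeds),
        "eigen_threshold": report.eigen_threshold,
        "core_sizes": report.core_sizes,
        "failed_replicates": report.failed_replicates,
        "versions": {
            "apyrel": apyrel.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    p = out / "run_metadata.yaml"
    _atomic_write(p, yaml.safe_dump(meta, sort_keys=False))
    written["metadata"] = p

    logp = out / "run.log"
    _atomic_write(
        logp,
        "\n".join(
            [f"replicates: {len(report.seeds)}", f"failed: {len(report.failed_replicates)}"]
        )
        + "\n",
    )
    written["log"] = logp
    return written


def read_stats_sidecar(path) -> pd.DataFrame:
    with open(path) as fh:
        return pd.DataFrame(json.load(fh))
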