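"""Readers and writers for every tabular format the pipeline touches.

All tabular files are UTF-8 TSV with mandatory headers.  Protein-protein
interactions are exchanged as 15-column PSI-MITAB 2.5 and gene sets as GMT.
Readers validate their input and raise :class:`ScreenIOError` naming the
offending row and column; writers always emit files their paired reader
accepts.  Gene/protein symbols are normalized (upper-cased, stripped) on read
so that human/mouse case conventions (EGFR vs Egfr) unify across sources.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("normoxia", "hypoxia_reoxygenation")
DMSO = "DMSO"

SHRNA_COLUMNS = ["shrna_id", "gene", "count_control", "count_treatment", "plasmid_expected"]
DRUG_PLATE_COLUMNS = ["drug", "concentration_nM", "condition", "rlu"]
DRUG_TARGET_COLUMNS = ["drug", "target", "interaction_term"]
EMBRYO_COLUMNS = ["group", "ef_percent", "heart_rate_bpm", "alive", "a_out", "a_in"]


class ScreenIOError(ValueError):
    """Malformed input file (missing column, bad value, duplicate key...)."""


def _norm_symbol(value: object) -> str:
    return str(value).strip().upper()


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScreenIOError(f"{path}: missing required column(s) {missing}")


def read_shrna_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-shRNA count table.

    Columns: shrna_id, gene, count_control, count_treatment, plasmid_expected.
    shrna_id must be unique, counts non-negative, plasmid_expected positive.
    """
    df = pd.read_csv(path, sep="\t", dtype={"shrna_id": str, "gene": str})
    _require_columns(df, SHRNA_COLUMNS, path)
    df = df[SHRNA_COLUMNS].copy()
    dup = df["shrna_id"].duplicated()
    if dup.any():
        row = int(dup.idxmax()) + 2  # header line is 1
        raise ScreenIOError(f"{path}: duplicate shrna_id {df.loc[dup.idxmax(), 'shrna_id']!r} at line {row}")
    if df["gene"].isna().any() or (df["gene"].astype(str).str.strip() == "").any():
        bad = df.index[df["gene"].isna() | (df["gene"].astype(str).str.strip() == "")][0]
        raise ScreenIOError(f"{path}: empty gene symbol at line {int(bad) + 2}")
    for col in ("count_control", "count_treatment"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = vals.index[vals.isna()][0]
            raise ScreenIOError(f"{path}: non-numeric value in column {col!r} at line {int(bad) + 2}")
        if (vals < 0).any():
            bad = vals.index[vals < 0][0]
            raise ScreenIOError(f"{path}: negative count in column {col!r} at line {int(bad) + 2}")
        df[col] = vals.astype(float)
    pe = pd.to_numeric(df["plasmid_expected"], errors="coerce")
    if pe.isna().any() or (pe <= 0).any():
        bad = pe.index[pe.isna() | (pe <= 0)][0]
        raise ScreenIOError(f"{path}: plasmid_expected must be positive, bad value at line {int(bad) + 2}")
    df["plasmid_expected"] = pe.astype(float)
    df["gene"] = df["gene"].map(_norm_symbol)
    return df.reset_index(drop=True)


def write_shrna_counts(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, SHRNA_COLUMNS, path)
    df[SHRNA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_drug_plates(path: str | Path) -> pd.DataFrame:
    """Read a plate-format viability table (drug, concentration_nM, condition, rlu)."""
    df = pd.read_csv(path, sep="\t", dtype={"drug": str, "condition": str})
    _require_columns(df, DRUG_PLATE_COLUMNS, path)
    df = df[DRUG_PLATE_COLUMNS].copy()
    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        bad = df.index[bad_cond][0]
        raise ScreenIOError(
            f"{path}: unknown condition {df.loc[bad, 'condition']!r} at line {int(bad) + 2};"
            f" expected one of {CONDITIONS}"
        )
    rlu = pd.to_numeric(df["rlu"], errors="coerce")
    if rlu.isna().any() or (rlu <= 0).any():
        bad = rlu.index[rlu.isna() | (rlu <= 0)][0]
        raise ScreenIOError(f"{path}: rlu must be positive, bad value at line {int(bad) + 2}")
    df["rlu"] = rlu.astype(float)
    df["concentration_nM"] = pd.to_numeric(df["concentration_nM"], errors="coerce").astype(float)
    # every non-DMSO drug must be observed in both conditions
    non_dmso = df[df["drug"] != DMSO]
    for drug, sub in non_dmso.groupby("drug"):
        present = set(sub["condition"])
        if present != set(CONDITIONS):
            raise ScreenIOError(f"{path}: drug {drug!r} lacks wells in condition(s) {set(CONDITIONS) - present}")
    return df.reset_index(drop=True)


def write_drug_plates(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, DRUG_PLATE_COLUMNS, path)
    df[DRUG_PLATE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_drug_targets(path: str | Path) -> pd.DataFrame:
    """Read drug->target annotations; duplicate (drug, target) pairs are dropped (first wins)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, DRUG_TARGET_COLUMNS, path)
    df = df[DRUG_TARGET_COLUMNS].copy()
    df["target"] = df["target"].map(_norm_symbol)
    df = df.drop_duplicates(subset=["drug", "target"], keep="first")
    return df.reset_index(drop=True)


def write_drug_targets(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, DRUG_TARGET_COLUMNS, path)
    df[DRUG_TARGET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into ``{pathway name: member list}``.

    Each line: name, description, then >= 1 tab-separated members.  The
    description field is accepted and discarded.  Duplicate pathway names and
    empty member lists are errors.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ScreenIOError(f"{path}: line {lineno}: need name, description and >=1 member")
            name = fields[0].strip()
            members = [_norm_symbol(m) for m in fields[2:] if m.strip()]
            if not members:
                raise ScreenIOError(f"{path}: line {lineno}: pathway {name!r} has no members")
            if name in sets:
                raise ScreenIOError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def _mitab_symbol(id_field: str, alias_field: str) -> str | None:
    """Resolve one interactor to a symbol: alias 'gene name' entries first, else the id text."""
    for entry in alias_field.split("|"):
        entry = entry.strip()
        if entry.endswith("(gene name)"):
            body = entry[: -len("(gene name)")]
            if ":" in body:
                body = body.split(":", 1)[1]
            body = body.strip()
            if body and body != "-":
                return _norm_symbol(body)
    id_field = id_field.strip()
    if id_field and id_field != "-":
        body = id_field.split("|", 1)[0]
        if ":" in body:
            body = body.split(":", 1)[1]
        body = body.strip()
        if body and body != "-":
            return _norm_symbol(body)
    return None


def read_mitab(path: str | Path) -> list[tuple[str, str]]:
    """Read PSI-MITAB 2.5 into an undirected, deduplicated edge list of symbol pairs.

    Uses the interactor identifier columns (1-2) and alias columns (5-6);
    'gene name' alias entries take precedence over raw identifiers.  Self
    interactions are dropped and rows without two resolvable symbols are
    skipped (counted and logged, never fatal).
    """
    edges: set[frozenset[str]] = set()
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                skipped += 1
                continue
            a = _mitab_symbol(fields[0], fields[4])
            b = _mitab_symbol(fields[1], fields[5])
            if a is None or b is None:
                skipped += 1
                continue
            if a == b:
                continue
            edges.add(frozenset((a, b)))
    if skipped:
        logger.warning("read_mitab: skipped %d row(s) without resolvable symbols", skipped)
    return sorted(tuple(sorted(e)) for e in edges)


def write_mitab(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write an edge list as minimal 15-column PSI-MITAB 2.5."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in edges:
            fields = ["-"] * 15
            fields[0] = f"uniprotkb:{a}"
            fields[1] = f"uniprotkb:{b}"
            fields[4] = f"uniprotkb:{a}(gene name)"
            fields[5] = f"uniprotkb:{b}(gene name)"
            fh.write("\t".join(fields) + "\n")


def read_embryos(path: str | Path) -> pd.DataFrame:
    """Read a per-embryo record table (group, ef_percent, heart_rate_bpm, alive, a_out, a_in)."""
    df = pd.read_csv(path, sep="\t", dtype={"group": str})
    _require_columns(df, EMBRYO_COLUMNS, path)
    df = df[EMBRYO_COLUMNS].copy()
    df["alive"] = df["alive"].astype(bool)
    for col in ("ef_percent", "heart_rate_bpm", "a_out", "a_in"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    bad = df["a_in"] > df["a_out"]
    if bad.any():
        raise ScreenIOError(f"{path}: a_in > a_out at line {int(df.index[bad][0]) + 2}")
    return df.reset_index(drop=True)


def write_embryos(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, EMBRYO_COLUMNS, path)
    df[EMBRYO_COLUMNS].to_csv(path, sep="\t", index=False)
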