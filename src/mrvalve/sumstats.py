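"""Reading, validating and filtering GWAS summary statistics.

A trait panel holds one trait's per-variant association estimates (effect
and other allele, effect-allele frequency, beta, SE, p, n).  For a
continuous exposure the betas are in SD units of the trait; for a binary
outcome they are log-odds.  Instrument selection applies a genome-wide
significance threshold followed by greedy distance-based pruning, so that
retained variants are at least ``window_bp`` apart on each chromosome.
LD-based pruning against a reference panel is out of scope: inputs are
assumed pre-pruned and the distance rule is a convenience.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SummaryRecord",
    "TraitPanel",
    "PanelFormatError",
    "PanelValidationError",
    "DEFAULT_COLUMNS",
    "read_panel",
    "write_panel",
    "select_instruments",
]

VALID_ALLELES = frozenset("ACGT")

#: default input column names -> canonical field names
DEFAULT_COLUMNS: dict[str, str] = {
    "SNP": "variant_id",
    "CHR": "chromosome",
    "POS": "position",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
}

CANONICAL_FIELDS = list(DEFAULT_COLUMNS.values())


class PanelFormatError(ValueError):
    """The file cannot be interpreted as a summary-statistics table."""


class PanelValidationError(ValueError):
    """Rows violate the per-record invariants; message lists row numbers."""


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association with one trait."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: Optional[float] = None
    n: Optional[float] = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        ea, oa = self.effect_allele, self.other_allele
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            problems.append(f"alleles must be single bases in ACGT, got {ea!r}/{oa!r}")
        elif ea == oa:
            problems.append(f"effect and other allele identical ({ea})")
        if not (self.se > 0):
            problems.append(f"se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            problems.append(f"eaf outside [0, 1]: {self.eaf}")
        if not (0.0 < self.pval <= 1.0):
            problems.append(f"pval outside (0, 1]: {self.pval}")
        if self.position < 1:
            problems.append(f"position must be >= 1, got {self.position}")
        return problems

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class TraitPanel:
    """A named collection of :class:`SummaryRecord` unique by variant id.

    ``data`` holds the canonical columns (``variant_id, chromosome,
    position, effect_allele, other_allele, eaf, beta, se, pval, n``);
    missing eaf / n are ``NaN``.
    """

    trait_name: str
    data: pd.DataFrame
    trait_type: str = "continuous"  # or "binary"
    sd_mmol_per_l: Optional[float] = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type}")
        missing = [c for c in CANONICAL_FIELDS if c not in self.data.columns]
        if missing:
            raise PanelFormatError(f"panel data missing columns: {missing}")
        ids = self.data["variant_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise PanelValidationError(f"duplicate variant ids: {dups}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.data["variant_id"])

    def records(self) -> dict[str, SummaryRecord]:
        out = {}
        for row in self.data.itertuples(index=False):
            rec = SummaryRecord(
                variant_id=row.variant_id,
                chromosome=str(row.chromosome),
                position=int(row.position),
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                n=None if pd.isna(row.n) else float(row.n),
            )
            out[rec.variant_id] = rec
        return out

    def subset(self, variant_ids) -> "TraitPanel":
        keep = self.data[self.data["variant_id"].isin(set(variant_ids))]
        return replace(self, data=keep.reset_index(drop=True))


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise PanelFormatError(f"{path}: header is neither tab- nor comma-delimited")


def panel_from_records(records, trait_name: str, **meta) -> TraitPanel:
    """Build a panel from an iterable of :class:`SummaryRecord`."""
    rows = []
    problems = []
    for i, rec in enumerate(records):
        errs = rec.validate()
        if errs:
            problems.append(f"record {i} ({rec.variant_id}): " + "; ".join(errs))
        rows.append(
            {
                "variant_id": rec.variant_id,
                "chromosome": rec.chromosome,
                "position": rec.position,
                "effect_allele": rec.effect_allele,
                "other_allele": rec.other_allele,
                "eaf": np.nan if rec.eaf is None else rec.eaf,
                "beta": rec.beta,
                "se": rec.se,
                "pval": rec.pval,
                "n": np.nan if rec.n is None else rec.n,
            }
        )
    if problems:
        raise PanelValidationError("invalid records:\n" + "\n".join(problems))
    df = pd.DataFrame(rows, columns=CANONICAL_FIELDS)
    return TraitPanel(trait_name=trait_name, data=df, **meta)


def read_panel(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    trait_name: Optional[str] = None,
    trait_type: str = "continuous",
    sd_mmol_per_l: Optional[float] = None,
) -> TraitPanel:
    """Read a delimited summary-statistics file into a validated panel.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.
    column_map
        Mapping from file column name to canonical field name; defaults to
        :data:`DEFAULT_COLUMNS`.  ``eaf`` and ``n`` columns are optional.

    Raises
    ------
    PanelFormatError
        Missing mapped columns or undetectable delimiter.
    PanelValidationError
        Rows violating record invariants; the message lists 1-based data
        row numbers and the offending values.
    """
    path = Path(path)
    cmap = dict(column_map) if column_map is not None else dict(DEFAULT_COLUMNS)
    sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, na_values=["NA", ""], keep_default_na=False)
    required = {k: v for k, v in cmap.items() if v not in ("eaf", "n")}
    missing = [k for k in required if k not in raw.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing mapped columns {missing}")
    present = {k: v for k, v in cmap.items() if k in raw.columns}
    df = raw[list(present)].rename(columns=present)
    for col in ("eaf", "n"):
        if col not in df.columns:
            df[col] = np.nan
    problems = []
    for col in ("position", "eaf", "beta", "se", "pval", "n"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & converted.isna()
        for idx in df.index[bad]:
            problems.append(f"row {idx + 1}: non-numeric {col} {df.at[idx, col]!r}")
        df[col] = converted
    if problems:
        raise PanelValidationError(f"{path}: malformed rows:\n" + "\n".join(problems))
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    df["chromosome"] = df["chromosome"].astype(str)
    df["position"] = df["position"].astype("int64")
    df = df[CANONICAL_FIELDS]

    for idx, row in df.iterrows():
        rec = SummaryRecord(
            variant_id=row["variant_id"],
            chromosome=row["chromosome"],
            position=int(row["position"]),
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            eaf=None if pd.isna(row["eaf"]) else float(row["eaf"]),
            n=None if pd.isna(row["n"]) else float(row["n"]),
        )
        for err in rec.validate():
            problems.append(f"row {idx + 1} ({rec.variant_id}): {err}")
    if problems:
        raise PanelValidationError(f"{path}: invalid rows:\n" + "\n".join(problems))
    return TraitPanel(
        trait_name=trait_name or path.stem,
        data=df,
        trait_type=trait_type,
        sd_mmol_per_l=sd_mmol_per_l,
    )


def write_panel(panel: TraitPanel, path, column_map: Optional[Mapping[str, str]] = None) -> None:
    """Write a panel as TSV; missing eaf/n become the sentinel ``NA``.

    Round-trips losslessly through :func:`read_panel`.
    """
    cmap = dict(column_map) if column_map is not None else dict(DEFAULT_COLUMNS)
    inverse = {v: k for k, v in cmap.items()}
    out = panel.data.rename(columns=inverse)
    # default float formatting is shortest-round-trip repr: lossless re-read
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def select_instruments(
    panel: TraitPanel, p_threshold: float = 5e-8, window_bp: int = 1_000_000
) -> TraitPanel:
    """Genome-wide significance filter followed by greedy distance pruning.

    Keeps records with ``pval < p_threshold``; then, per chromosome,
    repeatedly keeps the remaining record with the smallest p-value and
    discards every record strictly closer than ``window_bp`` to it.  Ties
    on p are broken by (chromosome, position, variant_id) so the result is
    independent of input row order.
    """
    df = panel.data
    sig = df[df["pval"] < p_threshold]
    if sig.empty:
        warnings.warn(
            f"{panel.trait_name}: no variants pass p < {p_threshold:g}", stacklevel=2
        )
        return replace(panel, data=sig.reset_index(drop=True))
    keep_ids = []
    order = sig.sort_values(
        ["pval", "chromosome", "position", "variant_id"], kind="mergesort"
    )
    for _, chrom_df in order.groupby("chromosome", sort=True):
        remaining = chrom_df
        while not remaining.empty:
            best = remaining.iloc[0]
            keep_ids.append(best["variant_id"])
            far = (remaining["position"] - best["position"]).abs() >= window_bp
            remaining = remaining[far]
    kept = df[df["variant_id"].isin(keep_ids)]
    kept = kept.sort_values(["chromosome", "position", "variant_id"], kind="mergesort")
    return replace(panel, data=kept.reset_index(drop=True))


def validation_report(panel: TraitPanel) -> dict:
    """Summary dict for the ``validate`` CLI subcommand."""
    df = panel.data
    return {
        "trait_name": panel.trait_name,
        "trait_type": panel.trait_type,
        "n_variants": int(len(df)),
        "n_missing_eaf": int(df["eaf"].isna().sum()),
        "n_missing_n": int(df["n"].isna().sum()),
        "n_palindromic": int(
            (
                (df["effect_allele"] + df["other_allele"]).isin(["AT", "TA", "CG", "GC"])
            ).sum()
        ),
        "chromosomes": sorted(df["chromosome"].unique().tolist()),
    }
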