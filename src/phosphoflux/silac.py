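"""Quantified phosphosite tables: IO, ratio normalization, significance, and
the tiered fold-change/significance filter cascade.

The central container is a pandas DataFrame, one row per quantified
phosphosite, with the schema:

========================  =====================================================
column                    meaning
========================  =====================================================
protein_id                protein accession
gene                      gene symbol (optional; falls back to protein_id)
position                  1-based residue index of the phosphosite
residue                   phosphorylated residue, one of S/T/Y
window                    15-mer sequence window centred on the site
loc_prob                  site-localization probability in [0, 1] (consumed)
log2_ratio_rep1..repN     per-replicate log2(H/L); H = high Cyclin A
protein_log2_ratio        protein-level log2(H/L) (optional)
p_value                   two-tailed significance (optional; computed if absent)
========================  =====================================================

Derived columns added by the pipeline: ``mean_log2`` (mean of available
normalized replicate ratios), ``n_quantified_reps``, ``motif_<name>`` flags,
``abundance_corrected``.

The filter cascade reproduces a tiered candidate-substrate screen: for each
kinase consensus motif, tier 1 keeps quantified sites matching the motif,
tier 2 additionally requires the mean log2 H/L ratio to reach the fold
threshold (default >= 1, i.e. at least two-fold more phosphorylated in the
high Cyclin A condition), and tier 3 additionally requires significance
(default p < 0.1).  An optional user-supplied gene list intersects each tier
with proteins of known mitotic function.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, EmptyInputError, SchemaError
from .motifs import BUILTIN_MOTIFS, MotifRule, annotate_motifs

REQUIRED_COLUMNS = ("protein_id", "position", "residue", "window")
RATIO_PATTERN = re.compile(r"^log2_ratio_rep(\d+)$")

__all__ = [
    "REQUIRED_COLUMNS",
    "ratio_columns",
    "read_site_table",
    "write_site_table",
    "median_center",
    "correct_protein_abundance",
    "collapse_duplicate_sites",
    "add_summary_columns",
    "fold_change_test",
    "add_pvalues",
    "CascadeResult",
    "apply_cascade",
    "write_cascade_report",
]


def ratio_columns(sites: pd.DataFrame) -> list[str]:
    """Replicate log2-ratio columns, in replicate order."""
    cols = [(int(m.group(1)), c) for c in sites.columns if (m := RATIO_PATTERN.match(c))]
    return [c for _, c in sorted(cols)]


def read_site_table(path, column_map: dict | None = None, sep: str = "\t") -> pd.DataFrame:
    """Read a quantified phosphosite table from TSV/CSV.

    ``column_map`` renames input columns to the package schema (e.g.
    ``{"Accession": "protein_id"}``), so exports from other pipelines can be
    consumed without editing files.  Rows with no quantified replicate are
    retained (they count as identified-but-unquantified); downstream tiers
    ignore them.  Raises :class:`SchemaError` naming the first missing
    required column, or the first non-numeric ratio cell with its row index.
    """
    table = pd.read_csv(path, sep=sep, dtype={"window": str})
    if column_map:
        table = table.rename(columns=column_map)
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    rcols = ratio_columns(table)
    if not rcols:
        raise SchemaError(
            f"no replicate ratio columns (log2_ratio_rep<N>) found in {path}"
        )
    for col in rcols + [c for c in ("protein_log2_ratio", "p_value") if c in table.columns]:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna() & (table[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"non-numeric value in column {col!r} at row {row}")
        table[col] = coerced
    table["position"] = table["position"].astype(int)
    return table


def write_site_table(sites: pd.DataFrame, path) -> None:
    """Write a site table as TSV; read_site_table round-trips it losslessly."""
    sites.to_csv(path, sep="\t", index=False, na_rep="")


def median_center(sites: pd.DataFrame, per_replicate: bool = True) -> pd.DataFrame:
    """Adjust replicate log2 H/L ratios for mixing errors by median centring.

    Subtracts each replicate column's median (default), or the pooled
    median of all quantified values (``per_replicate=False``).  After
    centring, the corresponding median is zero — exactly so for odd counts.
    """
    rcols = ratio_columns(sites)
    values = sites[rcols].to_numpy(dtype=float)
    if np.isnan(values).all():
        raise EmptyInputError("no quantified replicate ratios to centre")
    out = sites.copy()
    if per_replicate:
        out[rcols] = values - np.nanmedian(values, axis=0, keepdims=True)
    else:
        out[rcols] = values - np.nanmedian(values)
    return out


def correct_protein_abundance(sites: pd.DataFrame) -> pd.DataFrame:
    """Subtract the protein-level log2 H/L from each replicate ratio.

    Removes the component of a phosphopeptide ratio explained by a change
    in total protein abundance, leaving the phosphorylation-specific change.
    Sites without a protein-level ratio pass through unchanged and are
    flagged ``abundance_corrected = False``.
    """
    out = sites.copy()
    rcols = ratio_columns(out)
    if "protein_log2_ratio" in out.columns:
        prot = pd.to_numeric(out["protein_log2_ratio"], errors="coerce")
    else:
        prot = pd.Series(np.nan, index=out.index)
    corrected = prot.notna()
    shift = prot.fillna(0.0).to_numpy()[:, None]
    out[rcols] = out[rcols].to_numpy(dtype=float) - np.where(
        corrected.to_numpy()[:, None], shift, 0.0
    )
    out["abundance_corrected"] = corrected.to_numpy()
    return out


def collapse_duplicate_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows reporting the same protein/position to one unique site.

    The same phosphosite can be observed on several peptide forms; replicate
    ratios are averaged across those rows and the remaining columns are taken
    from the first occurrence, so "unique phosphorylation site" counts are
    well defined.
    """
    key = ["protein_id", "position"]
    if not sites.duplicated(key).any():
        return sites.copy()
    rcols = ratio_columns(sites)
    agg = {c: "mean" for c in rcols}
    for c in sites.columns:
        if c not in rcols and c not in key:
            agg[c] = "first"
    out = sites.groupby(key, as_index=False, sort=False).agg(agg)
    return out[list(sites.columns)]


def add_summary_columns(sites: pd.DataFrame) -> pd.DataFrame:
    """Add ``mean_log2`` and ``n_quantified_reps`` derived columns."""
    out = sites.copy()
    values = out[ratio_columns(out)].to_numpy(dtype=float)
    mask = ~np.isnan(values)
    n = mask.sum(axis=1)
    total = np.where(mask, values, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, total / n, np.nan)
    out["mean_log2"] = mean
    out["n_quantified_reps"] = n
    return out


def fold_change_test(
    values,
    mu0: float = 0.0,
    mode: str = "one_sample",
    reference=None,
) -> float:
    """Two-tailed t-test p-value for one site's replicate log2 ratios.

    ``one_sample`` tests the mean replicate ratio against ``mu0``;
    ``welch_vs_reference`` is Welch's unequal-variance two-sample test of the
    site's replicates against a supplied reference vector.  Returns ``nan``
    (not an exception) when fewer than two replicates are quantified or the
    sample variance is zero: such sites are not reproducibly quantified.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        return float("nan")
    if np.ptp(x) == 0.0:
        return float("nan")
    if mode == "one_sample":
        res = stats.ttest_1samp(x, popmean=mu0, alternative="two-sided")
    elif mode == "welch_vs_reference":
        if reference is None:
            raise ConfigurationError("welch_vs_reference requires a reference vector")
        ref = np.asarray(reference, dtype=float)
        ref = ref[~np.isnan(ref)]
        if ref.size < 2:
            return float("nan")
        res = stats.ttest_ind(x, ref, equal_var=False, alternative="two-sided")
    else:
        raise ConfigurationError(f"unknown test mode {mode!r}")
    return float(res.pvalue)


def add_pvalues(
    sites: pd.DataFrame,
    mu0: float = 0.0,
    mode: str = "one_sample",
    reference=None,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Fill the ``p_value`` column where absent.

    Tables that already carry deposited p-values are used verbatim unless
    ``overwrite`` is set; only missing entries are computed.  The one-sample
    test is vectorized across rows.
    """
    out = sites.copy()
    if "p_value" not in out.columns:
        out["p_value"] = np.nan
    need = out["p_value"].isna().to_numpy() if not overwrite else np.ones(len(out), bool)
    if not need.any():
        return out
    values = out[ratio_columns(out)].to_numpy(dtype=float)
    if mode == "one_sample":
        mask = ~np.isnan(values)
        n = mask.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            total = np.where(mask, values, 0.0).sum(axis=1)
            mean = total / n
            ss = np.where(mask, (values - mean[:, None]) ** 2, 0.0).sum(axis=1)
            sd = np.sqrt(ss / np.maximum(n - 1, 1))
            t = (mean - mu0) / (sd / np.sqrt(n))
            p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
        p[(n < 2) | (sd == 0) | ~np.isfinite(t)] = np.nan
    else:
        p = np.array(
            [fold_change_test(row, mu0=mu0, mode=mode, reference=reference) for row in values]
        )
    out.loc[need, "p_value"] = p[need]
    return out


@dataclass
class CascadeResult:
    """Tier counts and surviving site tables of the filter cascade.

    ``counts[motif]`` holds, per tier, the number of unique sites
    (``*_sites``) and unique proteins (``*_proteins``).  ``tier_tables`` maps
    ``(motif, tier)`` to the surviving rows; the counts are re-derivable from
    the tables.
    """

    n_quantified: int
    n_identified: int
    fold_threshold: float
    p_threshold: float
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    tier_tables: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    mitotic_list_used: bool = False


def _unique_counts(table: pd.DataFrame) -> tuple[int, int]:
    sites = len(table.drop_duplicates(["protein_id", "position"]))
    proteins = table["protein_id"].nunique()
    return sites, proteins


def apply_cascade(
    sites: pd.DataFrame,
    motif_rules=None,
    fold_threshold: float = 1.0,
    p_threshold: float = 0.1,
    mitotic_list=None,
    test_mode: str = "one_sample",
    reference=None,
    collapse_duplicates: bool = True,
) -> CascadeResult:
    """Run the tiered motif / fold-change / significance filter cascade.

    Per motif: tier ``motif`` keeps quantified sites whose window matches the
    consensus; tier ``fold`` additionally requires ``mean_log2 >=
    fold_threshold`` (signed: enrichment in the heavy, high-Cyclin-A
    condition); tier ``sig`` additionally requires a defined ``p_value <
    p_threshold``.  With a ``mitotic_list`` (iterable of gene symbols or
    accessions) each tier is intersected with proteins of known mitotic
    function.  Counts are monotone: sig <= fold <= motif <= quantified.
    """
    if motif_rules is None:
        motif_rules = list(BUILTIN_MOTIFS.values())
    motif_rules = list(motif_rules)
    if not motif_rules:
        raise ConfigurationError("apply_cascade needs at least one motif rule")
    rules: list[MotifRule] = [
        BUILTIN_MOTIFS[r] if isinstance(r, str) else r for r in motif_rules
    ]

    work = collapse_duplicate_sites(sites) if collapse_duplicates else sites.copy()
    work = add_summary_columns(work)
    missing = [r.name for r in rules if f"motif_{r.name}" not in work.columns]
    if missing:
        work = annotate_motifs(work, [r for r in rules if r.name in missing])
    work = add_pvalues(work, mode=test_mode, reference=reference)

    quantified = work[work["n_quantified_reps"] >= 1]
    result = CascadeResult(
        n_quantified=_unique_counts(quantified)[0],
        n_identified=_unique_counts(work)[0],
        fold_threshold=fold_threshold,
        p_threshold=p_threshold,
        mitotic_list_used=mitotic_list is not None,
    )

    mito = None
    if mitotic_list is not None:
        mito = {str(g).upper() for g in mitotic_list}

    for rule in rules:
        tier1 = quantified[quantified[f"motif_{rule.name}"]]
        tier2 = tier1[tier1["mean_log2"] >= fold_threshold]
        tier3 = tier2[tier2["p_value"].notna() & (tier2["p_value"] < p_threshold)]
        counts = {}
        for tier_name, table in (("motif", tier1), ("fold", tier2), ("sig", tier3)):
            s, p = _unique_counts(table)
            counts[f"{tier_name}_sites"], counts[f"{tier_name}_proteins"] = s, p
            result.tier_tables[(rule.name, tier_name)] = table.reset_index(drop=True)
        if mito is not None:
            gene_col = "gene" if "gene" in tier2.columns else "protein_id"
            def _in_list(tbl):
                ids = tbl[gene_col].astype(str).str.upper()
                acc = tbl["protein_id"].astype(str).str.upper()
                return tbl[ids.isin(mito) | acc.isin(mito)]
            for tier_name, table in (("fold", tier2), ("sig", tier3)):
                mtable = _in_list(table)
                s, p = _unique_counts(mtable)
                counts[f"mitotic_{tier_name}_sites"] = s
                counts[f"mitotic_{tier_name}_proteins"] = p
                result.tier_tables[(rule.name, f"mitotic_{tier_name}")] = (
                    mtable.reset_index(drop=True)
                )
        result.counts[rule.name] = counts
    return result


def write_cascade_report(result: CascadeResult, path) -> None:
    """Write tier counts and thresholds as YAML (human-readable audit trail)."""
    import yaml

    payload = {
        "n_identified_sites": int(result.n_identified),
        "n_quantified_sites": int(result.n_quantified),
        "fold_threshold": float(result.fold_threshold),
        "p_threshold": float(result.p_threshold),
        "mitotic_list_used": bool(result.mitotic_list_used),
        "motifs": {
            name: {k: int(v) for k, v in counts.items()}
            for name, counts in result.counts.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
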