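"""Couple-level inference.

The central test: for each man, take the UniFrac distance from his
specimen (penile skin or urethra) to his partner's vaginal specimen (the
partner distance) and the mean distance to every other woman's vaginal
specimen in the same clinical group (the non-partner distance); a paired
t-test across men then asks whether partners are systematically closer
than non-partners. The analysis is stratified by group (BV / normal),
male site, and circumcision status.

Also here: the >= 30 % prevalence filter, Spearman correlations of taxon
abundances across couples' sites, the Fisher-z comparison of two
correlations, and the contingency-table and abundance tests used for
cohort characterisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .types import MALE_SITES, OtuTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedDistanceRecord:
    male_specimen_id: str
    couple_id: str
    site: str
    group: str
    circumcised: bool | None
    partner_distance: float
    nonpartner_distance: float
    n_nonpartners: int


@dataclass(frozen=True)
class PartnerTestResult:
    group: str
    site: str
    circumcised: bool | None
    n_pairs: int
    mean_partner: float
    mean_nonpartner: float
    t: float
    p: float


@dataclass(frozen=True)
class OtuCorrelation:
    taxon: str
    site_pair: str  # "VG-PS" or "VG-UT"
    rho: float | None
    n_couples: int


def _metadata_lookup(metadata: pd.DataFrame) -> pd.DataFrame:
    required = {"specimen_id", "couple_id", "site", "group", "circumcised"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValidationError(f"metadata missing columns {sorted(missing)}")
    return metadata.set_index("specimen_id", drop=False)


def partner_nonpartner(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    male_site: str,
    group: str,
    restrict_to_group: bool = True,
    circumcised: bool | None = None,
) -> list[PairedDistanceRecord]:
    """Partner and mean non-partner distance for each man in a stratum.

    The non-partner pool is every other woman's vaginal specimen — by
    default only women of the same clinical group. Men missing their own
    or their partner's specimen are skipped with a logged note.
    """
    if male_site not in MALE_SITES:
        raise ValidationError(f"male_site must be one of {MALE_SITES}")
    meta = _metadata_lookup(metadata)
    have = set(dm.ids)
    men = meta[(meta["site"] == male_site) & (meta["group"] == group)]
    if circumcised is not None:
        men = men[men["circumcised"] == circumcised]
    women = meta[meta["site"] == "vagina"]
    if restrict_to_group:
        women = women[women["group"] == group]
    vaginal_by_couple = dict(zip(women["couple_id"], women["specimen_id"]))
    n_couples_in_group = len(
        set(meta.loc[(meta["site"] == "vagina") & (meta["group"] == group), "couple_id"])
    )
    if n_couples_in_group < 2:
        raise ValidationError(
            f"group {group!r} has fewer than 2 couples; no non-partners exist"
        )
    records = []
    for row in men.itertuples(index=False):
        if row.specimen_id not in have:
            logger.info("man %s skipped: specimen absent from distance matrix", row.specimen_id)
            continue
        partner = vaginal_by_couple.get(row.couple_id)
        if partner is None or partner not in have:
            logger.info("man %s skipped: partner vaginal specimen missing", row.specimen_id)
            continue
        others = [
            sid
            for cid, sid in vaginal_by_couple.items()
            if cid != row.couple_id and sid in have
        ]
        if not others:
            continue
        d_partner = float(dm[row.specimen_id, partner])
        d_others = float(np.mean([dm[row.specimen_id, sid] for sid in others]))
        records.append(
            PairedDistanceRecord(
                male_specimen_id=row.specimen_id,
                couple_id=row.couple_id,
                site=male_site,
                group=group,
                circumcised=row.circumcised,
                partner_distance=d_partner,
                nonpartner_distance=d_others,
                n_nonpartners=len(others),
            )
        )
    return records


def paired_partner_test(records: list[PairedDistanceRecord]) -> PartnerTestResult:
    """Two-sided paired t-test of partner vs non-partner distances."""
    if len(records) < 2:
        raise ValidationError("paired test needs at least 2 records")
    partner = np.array([r.partner_distance for r in records])
    nonpartner = np.array([r.nonpartner_distance for r in records])
    diffs = partner - nonpartner
    if np.allclose(diffs.var(ddof=0), 0.0):
        if np.allclose(diffs, 0.0):
            t, p = 0.0, 1.0
        else:
            raise ValidationError(
                "degenerate paired test: constant non-zero differences"
            )
    else:
        t, p = stats.ttest_rel(partner, nonpartner)
    first = records[0]
    circs = {r.circumcised for r in records}
    return PartnerTestResult(
        group=first.group,
        site=first.site,
        circumcised=circs.pop() if len(circs) == 1 else None,
        n_pairs=len(records),
        mean_partner=float(partner.mean()),
        mean_nonpartner=float(nonpartner.mean()),
        t=float(t),
        p=float(p),
    )


def stratified_partner_analysis(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    restrict_to_group: bool = True,
) -> list[PartnerTestResult]:
    """The partner test in all 8 strata: group x male site x circumcision.

    Empty strata (or strata with a single man) are reported as absent.
    """
    results = []
    for group in ("BV", "normal"):
        for site in MALE_SITES:
            for circ in (True, False):
                records = partner_nonpartner(
                    dm,
                    metadata,
                    male_site=site,
                    group=group,
                    restrict_to_group=restrict_to_group,
                    circumcised=circ,
                )
                if len(records) < 2:
                    continue
                results.append(paired_partner_test(records))
    return results


def prevalence_filter(
    table: OtuTable, specimen_ids, threshold: float = 0.30
) -> list[str]:
    """Taxa detected in strictly more than ``threshold`` of the subset."""
    ids = list(specimen_ids)
    if not ids:
        raise ValidationError("empty specimen subset")
    sub = table.subset_specimens(ids)
    prevalence = (sub.counts > 0).mean(axis=1)
    return [t for t, prev in zip(sub.taxa, prevalence) if prev > threshold]


SITE_PAIR_CODES = {"penile_skin": "VG-PS", "urethra": "VG-UT"}


def spearman_couple_correlations(
    table: OtuTable,
    metadata: pd.DataFrame,
    taxa: list[str],
    group: str,
    min_couples: int = 4,
) -> list[OtuCorrelation]:
    """Spearman rho between a taxon's relative abundance in the woman's
    vaginal specimen and in her partner's male-site specimen, across the
    group's complete couples; one record per taxon and site pair."""
    meta = _metadata_lookup(metadata)
    rel = pd.DataFrame(
        table.relative_abundance(), index=table.taxa, columns=table.specimen_ids
    )
    group_meta = meta[meta["group"] == group]
    by_couple_site: dict[tuple[str, str], str] = {
        (row.couple_id, row.site): row.specimen_id
        for row in group_meta.itertuples(index=False)
        if row.specimen_id in rel.columns
    }
    couples = sorted({cid for cid, _ in by_couple_site})
    out = []
    for male_site, code in SITE_PAIR_CODES.items():
        pairs = [
            (by_couple_site[(c, "vagina")], by_couple_site[(c, male_site)])
            for c in couples
            if (c, "vagina") in by_couple_site and (c, male_site) in by_couple_site
        ]
        for taxon in taxa:
            if len(pairs) < min_couples:
                out.append(OtuCorrelation(taxon, code, None, len(pairs)))
                continue
            x = rel.loc[taxon, [v for v, _ in pairs]].to_numpy()
            y = rel.loc[taxon, [m for _, m in pairs]].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                out.append(OtuCorrelation(taxon, code, None, len(pairs)))
                continue
            rho, _ = stats.spearmanr(x, y)
            out.append(OtuCorrelation(taxon, code, float(rho), len(pairs)))
    return out


def fisher_z_compare(
    rho1: float, n1: int, rho2: float, n2: int
) -> tuple[float, float]:
    """Compare two independent Spearman/Pearson correlations.

    z = (atanh(rho1) - atanh(rho2)) / sqrt(1/(n1-3) + 1/(n2-3)), with a
    two-sided normal p-value.
    """
    if abs(rho1) >= 1 or abs(rho2) >= 1:
        raise ValidationError("Fisher z transform undefined at |rho| = 1")
    if n1 <= 3 or n2 <= 3:
        raise ValidationError("need more than 3 observations per correlation")
    z = (np.arctanh(rho1) - np.arctanh(rho2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def contingency_test(table, method: str = "chi2") -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) or Fisher's exact
    test on a 2 x k contingency table."""
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise ValidationError("expected a 2 x k contingency table")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValidationError("contingency table must hold non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has a zero marginal")
    if method == "chi2":
        stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
        return float(stat), float(p)
    if method == "fisher":
        if arr.shape != (2, 2):
            raise ValidationError("Fisher's exact test supported for 2 x 2 tables")
        stat, p = stats.fisher_exact(arr, alternative="two-sided")
        return float(stat), float(p)
    raise ValueError(f"unknown method {method!r}")


def abundance_group_compare(
    table: OtuTable,
    specimens_a,
    specimens_b,
    taxa: list[str] | None = None,
    correct: bool = True,
) -> pd.DataFrame:
    """Per-taxon Mann-Whitney U on relative abundances between two
    specimen groups, with Benjamini-Hochberg q-values across taxa."""
    rel = pd.DataFrame(
        table.relative_abundance(), index=table.taxa, columns=table.specimen_ids
    )
    taxa = list(table.taxa) if taxa is None else taxa
    rows = []
    for taxon in taxa:
        x = rel.loc[taxon, list(specimens_a)].to_numpy()
        y = rel.loc[taxon, list(specimens_b)].to_numpy()
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            stat, p = len(x) * len(y) / 2.0, 1.0
        else:
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"taxon": taxon, "statistic": float(stat), "p": float(p)})
    df = pd.DataFrame(rows)
    if correct and len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = df["p"]
    return df
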