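"""Combined genetic effects and genetically corrected PSA risk scores.

A subject's *combined genetic effect* (CGE) is the product, over a panel of
SNPs, of each SNP's published relative effect raised to a genotype-derived
exponent.  For the four PSA-associated SNPs the relative effect is the
multiplicative change in circulating PSA per effect allele (e.g. +39.1% per
allele -> factor 1.391); for aggressive-disease SNPs it is a published odds
ratio.  The *genetically corrected PSA risk score* is then measured PSA minus
the CGE: a high score means a man's PSA exceeds what his genotype predicts,
which is the component of PSA potentially informative about disease.

Four genotype-to-exponent contrasts are supported:

``additive``
    exponent = dosage (0, 1 or 2 effect alleles).
``additive_shifted``
    exponent = dosage - 1.  Used for a locus where the zero-dosage class is
    absent from the data by design (the KLK3 locus rs17632542: homozygote
    non-carriers do not occur in the screened cohort, so one copy is the
    reference class).  A dosage of 0 is a hard error, never silently handled.
``dominant``
    exponent = 1 if dosage >= 1 else 0 (grouped-genotype contrast, e.g.
    "AC/CC vs AA").
``recessive``
    exponent = 1 if dosage == 2 else 0 (e.g. "TT vs GG/GT").

Panels are data, not code: the bundled 4-SNP PSA panel and 10-SNP
aggressive-disease panel live in ``psacorrect/panels/*.tsv`` and users may
supply their own files with the same columns.
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError, ValidationError

GENETIC_MODELS = ("additive", "additive_shifted", "dominant", "recessive")

__all__ = [
    "SNPDefinition",
    "Panel",
    "relative_effect_from_pct",
    "display_effect",
    "exponent_for",
    "combined_genetic_effect",
    "aggressive_combined_effect",
    "corrected_psa_score",
    "count_risk_alleles",
    "load_panel",
    "psa_panel",
    "aggressive_panel",
]


@dataclass(frozen=True)
class SNPDefinition:
    """One panel entry: effect allele, relative effect size and the genetic
    contrast used to turn a genotype dosage into an exponent.

    ``effect_size`` is a relative PSA factor for PSA-SNPs and an odds ratio
    for aggressive-disease SNPs; both enter the product as published
    (protective ORs < 1 are not inverted).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    effect_size: float
    genetic_model: str = "additive"
    locus_label: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ConfigError(f"{self.rsid}: effect_size must be > 0, got {self.effect_size}")
        if self.genetic_model not in GENETIC_MODELS:
            raise ConfigError(
                f"{self.rsid}: unknown genetic_model {self.genetic_model!r}; "
                f"expected one of {GENETIC_MODELS}"
            )


@dataclass(frozen=True)
class Panel:
    """Ordered collection of SNP definitions with unique rsIDs."""

    snps: tuple[SNPDefinition, ...]
    name: str = "panel"
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.rsid for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"panel {self.name!r}: duplicate rsIDs {ids}")

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    def __iter__(self) -> Iterator[SNPDefinition]:
        return iter(self.snps)

    def __len__(self) -> int:
        return len(self.snps)

    def __getitem__(self, rsid: str) -> SNPDefinition:
        for s in self.snps:
            if s.rsid == rsid:
                return s
        raise KeyError(rsid)

    def subset(self, rsids: Iterable[str]) -> "Panel":
        keep = list(rsids)
        return Panel(
            tuple(s for s in self.snps if s.rsid in keep),
            name=f"{self.name}[{','.join(keep)}]",
            provenance=self.provenance,
        )


def relative_effect_from_pct(pct_increase: float) -> float:
    """Convert a per-allele percent increase into a multiplicative factor.

    39.1 -> 1.391.  Full precision is kept internally; use
    :func:`display_effect` for the 2-decimal reporting convention.
    """
    if pct_increase <= -100:
        raise ConfigError(f"percent increase must exceed -100, got {pct_increase}")
    return 1.0 + pct_increase / 100.0


def display_effect(factor: float) -> float:
    """Round a relative effect to the 2-decimal display convention
    (1.391 -> 1.39, 1.105 -> 1.11: decimal half-up, not banker's/binary)."""
    from decimal import ROUND_HALF_UP, Decimal

    return float(Decimal(repr(float(factor))).quantize(Decimal("0.01"),
                                                       rounding=ROUND_HALF_UP))


def exponent_for(dosage: int, model: str, subject_id: str | None = None) -> int:
    """Genotype dosage -> exponent under a genetic-model contrast.

    Raises :class:`DataError` for dosage 0 under ``additive_shifted``: that
    genotype class is assumed absent and must surface as an error rather than
    be silently remapped.
    """
    d = _as_dosage(dosage, subject_id)
    if model == "additive":
        return d
    if model == "additive_shifted":
        if d == 0:
            who = f" (subject {subject_id})" if subject_id is not None else ""
            raise DataError(
                "dosage 0 encountered under the shifted-additive contrast"
                f"{who}: the zero-dosage class is assumed absent by design"
            )
        return d - 1
    if model == "dominant":
        return 1 if d >= 1 else 0
    if model == "recessive":
        return 1 if d == 2 else 0
    raise ConfigError(f"unknown genetic model {model!r}")


def _as_dosage(value, subject_id=None) -> int:
    try:
        d = int(value)
    except (TypeError, ValueError):
        d = -1
    if d != value or d not in (0, 1, 2):
        who = f" (subject {subject_id})" if subject_id is not None else ""
        raise ValidationError(f"dosage must be 0, 1 or 2, got {value!r}{who}")
    return d


def _exponents_vector(dosages: np.ndarray, snp: SNPDefinition, ids) -> np.ndarray:
    """Vectorised exponent_for over a dosage array; validates dosages."""
    d = np.asarray(dosages)
    if np.any(pd.isna(d)):
        bad = np.asarray(ids)[pd.isna(d)][:5]
        raise ValidationError(f"{snp.rsid}: missing dosage for subjects {list(bad)}")
    d = d.astype(float)
    if not np.all(np.isin(d, (0.0, 1.0, 2.0))):
        bad = np.asarray(ids)[~np.isin(d, (0.0, 1.0, 2.0))][:5]
        raise ValidationError(f"{snp.rsid}: dosage outside {{0,1,2}} for subjects {list(bad)}")
    d = d.astype(int)
    if snp.genetic_model == "additive":
        return d
    if snp.genetic_model == "additive_shifted":
        if np.any(d == 0):
            bad = np.asarray(ids)[d == 0][:5]
            raise DataError(
                f"{snp.rsid}: dosage 0 under the shifted-additive contrast "
                f"for subjects {list(bad)}; this genotype class is assumed absent"
            )
        return d - 1
    if snp.genetic_model == "dominant":
        return (d >= 1).astype(int)
    if snp.genetic_model == "recessive":
        return (d == 2).astype(int)
    raise ConfigError(f"unknown genetic model {snp.genetic_model!r}")


def combined_genetic_effect(genotypes, panel: Panel):
    """Product over panel SNPs of effect_size ** exponent(dosage).

    Parameters
    ----------
    genotypes
        Either a mapping ``rsid -> dosage`` for a single subject (returns a
        float) or a DataFrame with one dosage column per panel rsID, indexed
        by subject (returns a Series).
    panel
        The SNP panel carrying effect sizes and genetic models.
    """
    if isinstance(genotypes, Mapping):
        out = 1.0
        for snp in panel:
            if snp.rsid not in genotypes or pd.isna(genotypes[snp.rsid]):
                raise ValidationError(f"missing dosage for {snp.rsid}")
            out *= snp.effect_size ** exponent_for(genotypes[snp.rsid], snp.genetic_model)
        return out

    df = genotypes
    missing = [s.rsid for s in panel if s.rsid not in df.columns]
    if missing:
        raise ValidationError(f"genotype columns missing from table: {missing}")
    log_cge = np.zeros(len(df))
    for snp in panel:
        expo = _exponents_vector(df[snp.rsid].to_numpy(), snp, df.index.to_numpy())
        log_cge = log_cge + expo * np.log(snp.effect_size)
    return pd.Series(np.exp(log_cge), index=df.index, name="combined_genetic_effect")


# The aggressive-disease combined effect is the same product algebra applied
# to an odds-ratio panel with mixed additive/dominant/recessive contrasts.
aggressive_combined_effect = combined_genetic_effect


def corrected_psa_score(psa, cge, mode: str = "subtract"):
    """Genetically corrected PSA risk score.

    ``subtract`` (canonical): measured PSA minus the combined genetic effect,
    in ng/mL-like units.  ``divide`` is an opt-in, non-canonical variant
    (PSA / CGE) matching the antecedent literature's ratio correction.
    """
    psa_arr = np.asarray(psa, dtype=float)
    cge_arr = np.asarray(cge, dtype=float)
    if np.any(psa_arr <= 0):
        raise ValidationError("psa must be positive")
    if np.any(cge_arr <= 0):
        raise ValidationError("combined genetic effect must be positive")
    if mode == "subtract":
        out = psa_arr - cge_arr
    elif mode == "divide":
        out = psa_arr / cge_arr
    else:
        raise ConfigError(f"unknown correction mode {mode!r}; use 'subtract' or 'divide'")
    if np.isscalar(psa) and np.isscalar(cge):
        return float(out)
    return out


def count_risk_alleles(genotypes, panel: Panel):
    """Sum of raw effect-allele dosages over the panel (not the remapped
    exponents — a man with rs17632542 dosage 1 still contributes 1 here)."""
    if isinstance(genotypes, Mapping):
        total = 0
        for snp in panel:
            if snp.rsid not in genotypes or pd.isna(genotypes[snp.rsid]):
                raise ValidationError(f"missing dosage for {snp.rsid}")
            total += _as_dosage(genotypes[snp.rsid])
        return total
    df = genotypes
    missing = [s.rsid for s in panel if s.rsid not in df.columns]
    if missing:
        raise ValidationError(f"genotype columns missing from table: {missing}")
    counts = np.zeros(len(df), dtype=int)
    for snp in panel:
        d = _exponents_vector(df[snp.rsid].to_numpy(), _additive_view(snp), df.index.to_numpy())
        counts = counts + d
    return pd.Series(counts, index=df.index, name="risk_allele_count")


def _additive_view(snp: SNPDefinition) -> SNPDefinition:
    return SNPDefinition(snp.rsid, snp.effect_allele, snp.other_allele, snp.effect_size, "additive")


@dataclass
class ScoreResult:
    """Per-subject score bundle."""

    subject_id: str
    combined_genetic_effect: float
    corrected_score: float
    risk_allele_count: int


def score_table(df: pd.DataFrame, panel: Panel, psa_column: str = "psa",
                mode: str = "subtract") -> pd.DataFrame:
    """Compute CGE, corrected score and risk-allele count for every subject.

    ``df`` must carry a PSA column and one dosage column per panel rsID.
    Returns a DataFrame indexed like ``df``.
    """
    cge = combined_genetic_effect(df, panel)
    corrected = corrected_psa_score(df[psa_column].to_numpy(), cge.to_numpy(), mode=mode)
    alleles = count_risk_alleles(df, panel)
    return pd.DataFrame(
        {
            "combined_genetic_effect": cge,
            "corrected_score": corrected,
            "risk_allele_count": alleles,
        },
        index=df.index,
    )


# ---------------------------------------------------------------------------
# Panel files

_PANEL_COLUMNS = ["rsid", "effect_allele", "other_allele", "effect_size",
                  "genetic_model", "locus_label", "source"]


def load_panel(path, name: str | None = None) -> Panel:
    """Read a panel from TSV (columns: rsid, effect_allele, other_allele,
    effect_size, genetic_model[, locus_label, source]) or from JSON
    (a list of objects with those keys)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        tbl = pd.read_csv(path, sep="\t", dtype=str)
        for col in _PANEL_COLUMNS[:5]:
            if col not in tbl.columns:
                raise ConfigError(f"panel file {path} lacks required column {col!r}")
        records = tbl.to_dict(orient="records")
    snps = tuple(
        SNPDefinition(
            rsid=str(r["rsid"]),
            effect_allele=str(r["effect_allele"]),
            other_allele=str(r["other_allele"]),
            effect_size=float(r["effect_size"]),
            genetic_model=str(r.get("genetic_model", "additive")),
            locus_label=str(r.get("locus_label", "") or ""),
            source=str(r.get("source", "") or ""),
        )
        for r in records
    )
    return Panel(snps, name=name or path.stem, provenance=str(path))


def _bundled(fname: str, name: str) -> Panel:
    ref = resources.files("psacorrect") / "panels" / fname
    with resources.as_file(ref) as p:
        panel = load_panel(p, name=name)
    return Panel(panel.snps, name=name, provenance=f"bundled:{fname}")


def psa_panel() -> Panel:
    """The bundled 4-SNP PSA panel (TERT, FGFR2, TBX3, KLK3 loci)."""
    return _bundled("psa4.tsv", "psa4")


def aggressive_panel() -> Panel:
    """The bundled 10-SNP aggressive-disease odds-ratio panel."""
    return _bundled("aggressive10.tsv", "aggressive10")
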