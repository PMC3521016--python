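"""Weighted genetic scores and variance explained.

The score for individual i is S_i = sum_k beta_k x_ik where x_ik is the
effect-allele dosage in [0,2] and beta_k the signal's assigned effect
(marginal for primary signals, conditional for higher ranks).  Variance
explained is the squared Pearson correlation between S and the phenotype
residuals — identical to the R^2 of a univariate linear regression of the
residuals on the score — computed over all samples and within each sex
stratum.  Residuals come from an OLS adjustment of the raw trait on age,
sex and their interaction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InputError
from .stepwise import Signal

log = logging.getLogger(__name__)

_SEX_CODES = {"F": 0, "M": 1, "FEMALE": 0, "MALE": 1, "0": 0, "1": 1, 0: 0, 1: 1}


@dataclass
class GenotypeMatrix:
    """Effect-allele dosages, samples x markers, values in [0,2] or NaN."""

    sample_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    effect_alleles: list[str] | None = None
    other_alleles: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise InputError("dosage matrix shape does not match sample/marker lists")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad & ~np.isnan(self.dosages)):
            raise InputError("dosages must lie in [0,2]")
        self._col = {m: k for k, m in enumerate(self.marker_ids)}

    def column(self, marker_id: str) -> np.ndarray:
        return self.dosages[:, self._col[marker_id]]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._col


@dataclass(frozen=True)
class ScoreResult:
    """Variance explained by a genetic score in one stratum."""

    stratum: str  # all / female / male
    r2: float
    n: int


# -- input -----------------------------------------------------------------


def genotypes_from_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a dosage matrix: first column sample id, one column per marker."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise InputError(f"dosage matrix needs an id column plus markers: {path}")
    ids = df.iloc[:, 0].astype(str).tolist()
    markers = list(df.columns[1:])
    return GenotypeMatrix(ids, markers, df.iloc[:, 1:].to_numpy(dtype=np.float64))


def genotypes_from_vcf(path: str | Path) -> GenotypeMatrix:
    """Read dosages from VCF: FORMAT/DS when present, else ALT count from GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers, eff, oth, cols = [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        ds = v.format("DS")
        if ds is not None:
            col = np.asarray(ds, dtype=np.float64).reshape(-1)
        else:
            gts = np.asarray([g[:2] for g in v.genotypes], dtype=np.float64)
            gts[gts < 0] = np.nan
            col = gts.sum(axis=1)
        markers.append(v.ID or f"{v.CHROM}:{v.POS}")
        eff.append(v.ALT[0])
        oth.append(v.REF)
        cols.append(col)
    vcf.close()
    if not cols:
        raise InputError(f"no usable variants in genotype VCF: {path}")
    return GenotypeMatrix(samples, markers, np.column_stack(cols), eff, oth)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table with columns id, trait, age, sex."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"id", "trait", "age", "sex"}
    if not needed.issubset(df.columns):
        raise InputError(
            f"phenotype table must have columns {sorted(needed)}, got {list(df.columns)}"
        )
    return df


# -- adjustment ------------------------------------------------------------


def _code_sex(values: pd.Series) -> pd.Series:
    def code(v):
        key = v.upper() if isinstance(v, str) else v
        return _SEX_CODES.get(key, np.nan)

    return values.map(code)


def adjust_phenotype(pheno: pd.DataFrame) -> tuple[pd.Series, int]:
    """OLS residuals of trait on intercept, age, sex and age x sex.

    Rows with any missing field are dropped (count returned).  Residuals
    are indexed by sample id and have mean zero.
    """
    df = pheno.copy()
    df["sex"] = _code_sex(df["sex"])
    df["trait"] = pd.to_numeric(df["trait"], errors="coerce")
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    complete = df.dropna(subset=["id", "trait", "age", "sex"])
    n_dropped = len(df) - len(complete)
    if len(complete) < 3:
        raise InputError(f"need >= 3 complete phenotype rows, have {len(complete)}")
    if complete["age"].nunique() < 2 or complete["sex"].nunique() < 2:
        raise InputError("age and sex must both vary for the adjustment model")
    X = sm.add_constant(
        pd.DataFrame(
            {
                "age": complete["age"],
                "sex": complete["sex"],
                "age_sex": complete["age"] * complete["sex"],
            }
        )
    )
    fit = sm.OLS(complete["trait"].to_numpy(), X.to_numpy()).fit()
    resid = pd.Series(fit.resid, index=complete["id"].astype(str))
    resid -= resid.mean()
    if n_dropped:
        log.info("adjust_phenotype: dropped %d incomplete rows", n_dropped)
    return resid, n_dropped


# -- scoring ---------------------------------------------------------------


def build_score(
    signals: list[Signal],
    genotypes: GenotypeMatrix,
    missing_policy: str = "rescale",
) -> pd.Series:
    """Weighted genetic score per sample.

    Signals whose markers are absent from the genotypes are dropped with a
    warning.  If a signal's effect allele is the genotype matrix's *other*
    allele the dosage is reflected (2 - x).  Missing dosages are handled by
    ``missing_policy``: ``"rescale"`` scales each sample's partial score by
    total |weight| / observed |weight|; ``"strict"`` sets the sample's
    score to NaN.
    """
    if missing_policy not in ("rescale", "strict"):
        raise InputError(f"unknown missing_policy: {missing_policy!r}")
    used: list[tuple[float, np.ndarray]] = []
    for sig in signals:
        if sig.marker_id not in genotypes:
            warnings.warn(f"signal marker {sig.marker_id} absent from genotypes; dropped",
                          stacklevel=2)
            continue
        dose = genotypes.column(sig.marker_id).astype(np.float64)
        if genotypes.effect_alleles is not None:
            k = genotypes._col[sig.marker_id]
            if sig.effect_allele != genotypes.effect_alleles[k]:
                if (genotypes.other_alleles is not None
                        and sig.effect_allele == genotypes.other_alleles[k]):
                    dose = 2.0 - dose
                else:
                    warnings.warn(
                        f"signal {sig.marker_id}: effect allele "
                        f"{sig.effect_allele} matches neither genotype allele; dropped",
                        stacklevel=2)
                    continue
        used.append((sig.effect.beta, dose))
    if not used:
        raise InputError("no overlap between signal markers and genotype matrix")

    weights = np.array([w for w, _ in used])
    mat = np.column_stack([d for _, d in used])
    observed = ~np.isnan(mat)
    contrib = np.where(observed, mat, 0.0) * weights
    score = contrib.sum(axis=1)
    if missing_policy == "rescale":
        total_w = np.abs(weights).sum()
        if total_w > 0:
            obs_w = (observed * np.abs(weights)).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                score = np.where(obs_w > 0, score * (total_w / obs_w), np.nan)
    else:
        score = np.where(observed.all(axis=1), score, np.nan)
    return pd.Series(score, index=pd.Index(genotypes.sample_ids, name="id"))


def variance_explained(
    score: pd.Series,
    residuals: pd.Series,
    sex: pd.Series | None = None,
) -> list[ScoreResult]:
    """Squared Pearson correlation of score and residuals, overall and by sex.

    ``sex`` (indexed by sample id, F/M or 0/1) triggers female/male strata.
    A zero-variance score yields r2 = 0 with a warning.
    """
    common = score.index.intersection(residuals.index)
    if len(common) < 3:
        raise InputError("need >= 3 samples with both score and residual")
    s = score.loc[common].to_numpy()
    y = residuals.loc[common].to_numpy()
    ok = ~(np.isnan(s) | np.isnan(y))

    def r2_of(mask) -> ScoreResult | None:
        n = int(mask.sum())
        if n < 3:
            return None
        ss, yy = s[mask], y[mask]
        if np.std(ss) == 0 or np.std(yy) == 0:
            warnings.warn("zero-variance score or residuals; r2 set to 0", stacklevel=3)
            return ScoreResult("", 0.0, n)
        r = np.corrcoef(ss, yy)[0, 1]
        return ScoreResult("", float(r * r), n)

    results = []
    overall = r2_of(ok)
    if overall is None:
        raise InputError("need >= 3 non-missing paired observations")
    results.append(ScoreResult("all", overall.r2, overall.n))
    if sex is not None:
        coded = _code_sex(sex.reindex(common))
        for label, code in (("female", 0), ("male", 1)):
            res = r2_of(ok & (coded.to_numpy() == code))
            if res is not None:
                results.append(ScoreResult(label, res.r2, res.n))
    return results


def score_report(
    signals_by_alpha: dict[float, list[Signal]],
    genotypes: GenotypeMatrix,
    residuals: pd.Series,
    sex: pd.Series | None = None,
    max_rank: int = 3,
) -> pd.DataFrame:
    """Variance explained by alpha x rank-inclusion x stratum.

    Rows are significance levels; for each, scores built from signals of
    rank <= 1, <= 2, ... <= max_rank are evaluated overall and per sex
    stratum, mirroring the usual primary / +secondary / +tertiary layout.
    """
    rows = []
    for alpha in sorted(signals_by_alpha):
        signals = signals_by_alpha[alpha]
        row: dict = {"alpha": alpha}
        for r in range(1, max_rank + 1):
            subset = [s for s in signals if s.rank <= r]
            row[f"n_snps_rank{r}"] = len(subset)
            if not subset:
                continue
            score = build_score(subset, genotypes)
            for res in variance_explained(score, residuals, sex=sex):
                row[f"r2_{res.stratum}_rank{r}"] = res.r2
        rows.append(row)
    return pd.DataFrame(rows)
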