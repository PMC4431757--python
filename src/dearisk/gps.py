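"""Weighted genetic predisposition score (GPS) from SNP effect-allele dosages.

The GPS over L loci with GWAS effect sizes beta_l and per-subject dosages
a_l in [0, 2] is the weighted allele count rescaled back to the allele-count
scale:

    GPS = [ sum_l a_l * beta_l / (2 * sum_l beta_l) ] * 2L
        = L * sum_l a_l beta_l / sum_l beta_l

so GPS is bounded by [0, 2L] (58 for the reference configuration L = 29) and
reduces to the plain allele count when all weights are equal.  Higher scores
indicate greater genetic predisposition to obesity.

Quality control follows the two standard chip-level filters: loci with minor
allele frequency < 0.5% or call rate < 95% are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SNPWeight",
    "SNPWeightSet",
    "GenotypeMatrix",
    "QCReport",
    "qc_filter_snps",
    "dosages_from_vcf",
    "compute_gps",
]


class GPSValidationError(ValueError):
    pass


@dataclass(frozen=True)
class SNPWeight:
    snp_id: str
    effect_allele: str
    beta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise GPSValidationError(
                f"SNP {self.snp_id!r}: beta must be > 0, got {self.beta}"
            )


class SNPWeightSet:
    """Ordered list of SNP weights with unique ids; TSV round-trippable."""

    def __init__(self, weights):
        weights = list(weights)
        if not weights:
            raise GPSValidationError("SNPWeightSet requires at least one SNP")
        ids = [w.snp_id for w in weights]
        if len(set(ids)) != len(ids):
            raise GPSValidationError("duplicate snp_id in SNPWeightSet")
        self.weights = weights
        self.snp_ids = ids
        self.betas = np.array([w.beta for w in weights], dtype=float)

    def __len__(self) -> int:
        return len(self.weights)

    def __iter__(self):
        return iter(self.weights)

    def subset(self, snp_ids) -> "SNPWeightSet":
        keep = set(snp_ids)
        return SNPWeightSet(w for w in self.weights if w.snp_id in keep)

    @classmethod
    def from_tsv(cls, path) -> "SNPWeightSet":
        df = pd.read_csv(path, sep="\t")
        required = {"snp_id", "effect_allele", "beta"}
        if not required.issubset(df.columns):
            raise GPSValidationError(
                f"weights TSV must have columns {sorted(required)}"
            )
        return cls(
            SNPWeight(str(r.snp_id), str(r.effect_allele), float(r.beta))
            for r in df.itertuples()
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "snp_id": self.snp_ids,
            "effect_allele": [w.effect_allele for w in self.weights],
            "beta": self.betas,
        }).to_csv(path, sep="\t", index=False)


@dataclass
class QCReport:
    retained: list[str]
    excluded_maf: list[str]
    excluded_call_rate: list[str]

    @property
    def excluded(self) -> list[str]:
        return sorted(set(self.excluded_maf) | set(self.excluded_call_rate))


class GenotypeMatrix:
    """Subjects x loci effect-allele dosages in [0, 2]; NaN marks missing.

    Minor-allele frequency and call rate are computed from the dosage matrix
    unless explicit per-SNP values are supplied (e.g. from upstream chip QC).
    """

    def __init__(self, dosages: pd.DataFrame,
                 maf: pd.Series | None = None,
                 call_rate: pd.Series | None = None):
        vals = dosages.to_numpy(dtype=float)
        if vals.size and not np.isnan(vals).all():
            with np.errstate(invalid="ignore"):
                if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
                    raise GPSValidationError("dosages must lie in [0, 2]")
        self.dosages = dosages.astype(float)
        self._maf = maf
        self._call_rate = call_rate

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.dosages.index.astype(str))

    @property
    def call_rate(self) -> pd.Series:
        if self._call_rate is not None:
            return self._call_rate
        return self.dosages.notna().mean(axis=0)

    @property
    def effect_allele_freq(self) -> pd.Series:
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    @property
    def maf(self) -> pd.Series:
        if self._maf is not None:
            return self._maf
        p = self.effect_allele_freq
        return np.minimum(p, 1.0 - p)

    def subset(self, snp_ids) -> "GenotypeMatrix":
        maf = self._maf.loc[snp_ids] if self._maf is not None else None
        cr = (self._call_rate.loc[snp_ids]
              if self._call_rate is not None else None)
        return GenotypeMatrix(self.dosages[list(snp_ids)], maf=maf,
                              call_rate=cr)

    @classmethod
    def from_csv(cls, path) -> "GenotypeMatrix":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.dosages.to_csv(path, index_label="subject_id")


def qc_filter_snps(
    geno: GenotypeMatrix,
    maf_min: float = 0.005,
    call_rate_min: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop loci with MAF < maf_min or call rate < call_rate_min.

    Column order of the retained loci is preserved.  An empty result is
    allowed (with a warning), never an error.
    """
    maf = geno.maf
    cr = geno.call_rate
    bad_maf = [s for s in geno.snp_ids if maf[s] < maf_min]
    bad_cr = [s for s in geno.snp_ids if cr[s] < call_rate_min]
    bad = set(bad_maf) | set(bad_cr)
    keep = [s for s in geno.snp_ids if s not in bad]
    if not keep:
        warnings.warn("QC filter removed every SNP", stacklevel=2)
        filtered = GenotypeMatrix(geno.dosages.iloc[:, :0])
    else:
        filtered = geno.subset(keep)
    return filtered, QCReport(keep, bad_maf, bad_cr)


def dosages_from_vcf(vcf_path, weights: SNPWeightSet) -> tuple[
        GenotypeMatrix, list[str]]:
    """Read effect-allele dosages for the weighted loci from a VCF.

    Uses the DS FORMAT field when present, otherwise counts effect alleles
    in GT.  The orientation is flipped (dosage = 2 - alt count) when the
    effect allele is the REF allele.  Missing genotypes stay missing and
    lower the locus call rate.  Multiallelic records are skipped with a
    warning; weighted loci absent from the VCF are returned as a
    missing-SNP report rather than raising.
    """
    from cyvcf2 import VCF

    wanted = {w.snp_id: w for w in weights}
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for rec in vcf:
        if rec.ID not in wanted or rec.ID in columns:
            continue
        w = wanted[rec.ID]
        if len(rec.ALT) != 1:
            warnings.warn(
                f"skipping multiallelic record {rec.ID}", stacklevel=2
            )
            continue
        if w.effect_allele == rec.ALT[0]:
            flip = False
        elif w.effect_allele == rec.REF:
            flip = True
        else:
            warnings.warn(
                f"effect allele {w.effect_allele} of {rec.ID} matches "
                "neither REF nor ALT; skipping", stacklevel=2
            )
            continue
        try:
            ds = np.asarray(rec.format("DS"), dtype=float).ravel()
            alt_dosage = ds
        except (TypeError, KeyError):
            gts = rec.genotype.array()  # rows: [allele_1, allele_2, phased]
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan  # -1 encodes missing
            alt_dosage = alleles.sum(axis=1)
        columns[rec.ID] = 2.0 - alt_dosage if flip else alt_dosage
    vcf.close()
    missing = [s for s in weights.snp_ids if s not in columns]
    frame = pd.DataFrame(
        {s: columns[s] for s in weights.snp_ids if s in columns},
        index=pd.Index(samples, name="subject_id"),
    )
    return GenotypeMatrix(frame), missing


def compute_gps(
    dosages: np.ndarray | pd.DataFrame | GenotypeMatrix,
    weights: SNPWeightSet,
    missing: str = "renormalize",
) -> np.ndarray | float:
    """Weighted genetic predisposition score, GPS = L * (a.beta) / sum(beta).

    Parameters
    ----------
    dosages : vector of L dosages, or a subjects x L matrix/GenotypeMatrix
        whose columns line up with ``weights`` (matrix columns are matched
        to snp_ids by name).
    missing : "renormalize" rescales per subject by the betas of the
        observed loci (keeping the [0, 2L] scale); "fail" raises on any
        missing dosage.

    Returns a scalar for a 1-D dosage vector, else one score per subject.
    """
    if missing not in ("renormalize", "fail"):
        raise ValueError(f"unknown missing policy {missing!r}")
    if isinstance(dosages, GenotypeMatrix):
        dosages = dosages.dosages
    if isinstance(dosages, pd.DataFrame):
        missing_cols = [s for s in weights.snp_ids if s not in dosages.columns]
        if missing_cols:
            raise GPSValidationError(
                f"dosage matrix lacks weighted loci: {missing_cols}"
            )
        A = dosages[weights.snp_ids].to_numpy(dtype=float)
    else:
        A = np.asarray(dosages, dtype=float)
    scalar = A.ndim == 1
    A = np.atleast_2d(A)
    L = len(weights)
    if A.shape[1] != L:
        raise GPSValidationError(
            f"dosage vector length {A.shape[1]} != number of weights {L}"
        )
    with np.errstate(invalid="ignore"):
        if np.nanmin(A) < 0 or np.nanmax(A) > 2:
            raise GPSValidationError("dosages must lie in [0, 2]")
    beta = weights.betas
    obs = ~np.isnan(A)
    if missing == "fail" and not obs.all():
        bad = np.where(~obs.all(axis=1))[0]
        raise GPSValidationError(
            f"missing dosages for subject rows {bad.tolist()} "
            "(missing policy is 'fail')"
        )
    num = np.nansum(A * beta, axis=1)
    denom = (obs * beta).sum(axis=1)
    if np.any(denom <= 0):
        raise GPSValidationError("no observed loci for at least one subject")
    gps = L * num / denom
    return float(gps[0]) if scalar else gps
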