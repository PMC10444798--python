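"""Colony QC and depth-sensitive genotype calling.

Each colony genome derives from a single founding cell, so a true somatic
variant is heterozygous and should appear at variant allele fraction (VAF)
~0.5 in a clonal, diploid colony. Genotypes are called per site per colony
by comparing two binomial likelihoods for the mutant read count MTR given
the depth DEP:

    mutant:    MTR ~ Binomial(DEP, expected VAF)
    wild-type: MTR ~ Binomial(DEP, error rate)

The call is the state whose likelihood exceeds the other by at least a
fixed ratio (default 20x); otherwise the genotype is missing (NA). The
expected VAF is 0.5 on diploid autosomes and 1/ploidy on sex chromosomes
or within copy-number-altered regions; absent calls inside a colony's
loss-of-heterozygosity intervals are overridden to NA because the wild-type
allele itself may have been lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, EmptyResultError

__all__ = [
    "ReadCountSet",
    "GenotypeMatrix",
    "qc_colonies",
    "call_genotype",
    "build_genotype_matrix",
]

SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


def _empty_regions(extra: tuple[str, ...] = ()) -> pd.DataFrame:
    return pd.DataFrame(columns=["colony", "chrom", "start", "end", *extra])


@dataclass
class ReadCountSet:
    """Mutant-read (MTR) and depth (DEP) matrices with site/colony metadata.

    ``mtr`` and ``dep`` are sites x colonies integer DataFrames sharing
    index (site ids) and columns (colony ids). ``sites`` is indexed by
    site id with columns chrom, pos (1-based), ref, alt, context
    (trinucleotide around the site), gene, consequence, is_germline.
    ``colonies`` is indexed by colony id with columns individual and
    age_years (median_vaf is added by QC). Ploidy and LOH intervals are
    1-based closed intervals per colony.
    """

    mtr: pd.DataFrame
    dep: pd.DataFrame
    sites: pd.DataFrame
    colonies: pd.DataFrame
    ploidy_regions: pd.DataFrame = field(default_factory=lambda: _empty_regions(("ploidy",)))
    loh_regions: pd.DataFrame = field(default_factory=_empty_regions)

    def __post_init__(self):
        if not (self.mtr.index.equals(self.dep.index) and self.mtr.columns.equals(self.dep.columns)):
            raise DataError("MTR and DEP matrices must share index and columns")
        if (self.mtr.values > self.dep.values).any():
            raise DataError("MTR exceeds DEP at some entries")
        if (self.mtr.values < 0).any() or (self.dep.values < 0).any():
            raise DataError("negative read counts")
        key = self.sites[["chrom", "pos", "ref", "alt"]]
        if key.duplicated().any():
            raise DataError("duplicate site records by (chrom, pos, ref, alt)")

    @property
    def colony_ids(self) -> list[str]:
        return list(self.mtr.columns)

    @property
    def somatic_ids(self) -> pd.Index:
        return self.sites.index[~self.sites["is_germline"]]

    @property
    def germline_ids(self) -> pd.Index:
        return self.sites.index[self.sites["is_germline"]]

    def subset_colonies(self, keep: list[str]) -> "ReadCountSet":
        return ReadCountSet(
            mtr=self.mtr[keep],
            dep=self.dep[keep],
            sites=self.sites,
            colonies=self.colonies.loc[keep],
            ploidy_regions=self.ploidy_regions[self.ploidy_regions["colony"].isin(keep)],
            loh_regions=self.loh_regions[self.loh_regions["colony"].isin(keep)],
        )


@dataclass
class GenotypeMatrix:
    """Sites x colonies genotypes: 1.0 present, 0.0 absent, NaN missing."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        out = self.data.replace({1.0: "1", 0.0: "0"}).fillna("NA")
        out.to_csv(path, sep="\t")


def call_genotype(mtr, dep, expected_vaf, error_rate: float = 0.01, ratio_threshold: float = 20.0):
    """Likelihood-ratio genotype call; vectorised over mtr/dep/expected_vaf.

    Returns 1.0 (present) if the mutant model is at least ``ratio_threshold``
    times more likely than the wild-type model, 0.0 (absent) for the
    converse, NaN otherwise (including zero depth). Ties at exactly the
    threshold count as decided.
    """
    mtr = np.asarray(mtr)
    dep = np.asarray(dep)
    vaf = np.asarray(expected_vaf, dtype=float)
    if np.any((vaf <= 0) | (vaf > 1)):
        raise ValueError("expected_vaf must lie in (0, 1]")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must lie in [0, 1)")
    if np.any(mtr < 0) or np.any(mtr > dep):
        raise ValueError("require 0 <= mtr <= dep")
    with np.errstate(divide="ignore"):
        l1 = stats.binom.logpmf(mtr, dep, vaf)
        l0 = stats.binom.logpmf(mtr, dep, error_rate)
    thr = np.log(ratio_threshold)
    diff = l1 - l0
    out = np.full(np.broadcast(mtr, dep, vaf).shape, np.nan)
    out[diff >= thr] = 1.0
    out[-diff >= thr] = 0.0
    out[np.broadcast_to(dep, out.shape) == 0] = np.nan
    if out.ndim == 0 or (np.isscalar(mtr) and np.isscalar(dep)):
        return float(out.reshape(-1)[0])
    return out


def _median_somatic_vaf(rc: ReadCountSet, colony: str, min_site_depth: int = 4) -> float:
    """Median VAF over somatic sites the colony carries (quick call = 1) at dep >= 4."""
    som = rc.somatic_ids
    m = rc.mtr.loc[som, colony].to_numpy()
    d = rc.dep.loc[som, colony].to_numpy()
    ok = d >= min_site_depth
    if not ok.any():
        return np.nan
    calls = call_genotype(m[ok], d[ok], 0.5)
    carried = calls == 1.0
    if not np.any(carried):
        return np.nan
    return float(np.median(m[ok][carried] / d[ok][carried]))


def qc_colonies(
    rc: ReadCountSet, min_depth: float = 6.0, min_median_vaf: float = 0.4
) -> tuple[ReadCountSet, pd.DataFrame]:
    """Remove low-depth and low-clonality colonies.

    Colonies with mean depth strictly below ``min_depth`` or median somatic
    VAF strictly below ``min_median_vaf`` are dropped (boundary values are
    retained). Returns the filtered set, with ``median_vaf`` recorded on the
    colony table, plus a per-colony QC report.
    """
    if rc.mtr.shape[1] == 0:
        raise EmptyResultError("no colonies in input")
    rows = []
    for colony in rc.colony_ids:
        mean_depth = float(rc.dep[colony].mean())
        med_vaf = _median_somatic_vaf(rc, colony)
        reasons = []
        if mean_depth < min_depth:
            reasons.append(f"mean depth {mean_depth:.2f} < {min_depth}")
        if np.isnan(med_vaf) or med_vaf < min_median_vaf:
            reasons.append(f"median VAF {med_vaf:.3f} < {min_median_vaf}")
        rows.append(
            {
                "colony": colony,
                "mean_depth": mean_depth,
                "median_vaf": med_vaf,
                "kept": not reasons,
                "reason": "; ".join(reasons),
            }
        )
    report = pd.DataFrame(rows).set_index("colony")
    keep = report.index[report["kept"]].tolist()
    if not keep:
        raise EmptyResultError("QC removed every colony")
    out = rc.subset_colonies(keep)
    colonies = out.colonies.copy()
    colonies["median_vaf"] = report.loc[keep, "median_vaf"]
    out = ReadCountSet(out.mtr, out.dep, out.sites, colonies, out.ploidy_regions, out.loh_regions)
    return out, report


def _region_lookup(regions: pd.DataFrame, colony: str, sites: pd.DataFrame) -> np.ndarray:
    """Boolean mask over sites falling in any of the colony's intervals."""
    mask = np.zeros(len(sites), dtype=bool)
    sub = regions[regions["colony"] == colony]
    for _, r in sub.iterrows():
        hit = (
            (sites["chrom"].astype(str) == str(r["chrom"]))
            & (sites["pos"] >= r["start"])
            & (sites["pos"] <= r["end"])
        )
        mask |= hit.to_numpy()
    return mask


def build_genotype_matrix(
    rc: ReadCountSet, error_rate: float = 0.01, ratio_threshold: float = 20.0
) -> GenotypeMatrix:
    """Call the full sites x colonies genotype matrix.

    Expected VAF is 0.5 on diploid autosomes and 1/ploidy on X, Y and
    per-colony copy-number regions; absent calls inside a colony's LOH
    intervals become NA.
    """
    sites = rc.sites
    n_sites = len(sites)
    data = {}
    for colony in rc.colony_ids:
        vaf = np.full(n_sites, 0.5)
        sex = sites["chrom"].astype(str).isin(SEX_CHROMS).to_numpy()
        vaf[sex] = 1.0
        sub = rc.ploidy_regions[rc.ploidy_regions["colony"] == colony]
        seen = np.full(n_sites, np.nan)
        for _, r in sub.iterrows():
            hit = (
                (sites["chrom"].astype(str) == str(r["chrom"]))
                & (sites["pos"] >= r["start"])
                & (sites["pos"] <= r["end"])
            ).to_numpy()
            conflict = hit & ~np.isnan(seen) & (seen != float(r["ploidy"]))
            if conflict.any():
                raise DataError(
                    f"colony {colony}: overlapping ploidy intervals disagree at "
                    f"{int(conflict.sum())} site(s)"
                )
            seen[hit] = float(r["ploidy"])
            if float(r["ploidy"]) <= 0:
                raise DataError(f"colony {colony}: non-positive ploidy interval")
            vaf[hit] = 1.0 / float(r["ploidy"])
        calls = call_genotype(
            rc.mtr[colony].to_numpy(),
            rc.dep[colony].to_numpy(),
            vaf,
            error_rate=error_rate,
            ratio_threshold=ratio_threshold,
        )
        loh = _region_lookup(rc.loh_regions, colony, sites)
        calls = np.where(loh & (calls == 0.0), np.nan, calls)
        data[colony] = calls
    df = pd.DataFrame(data, index=sites.index)
    return GenotypeMatrix(
        df, provenance={"error_rate": error_rate, "ratio_threshold": ratio_threshold}
    )


# -- plain-text IO -------------------------------------------------------


def read_fixture(directory) -> ReadCountSet:
    """Load the TSV fixture layout written by :func:`colonyphylo.simdata.write_fixture`."""
    d = Path(directory)
    mtr = pd.read_csv(d / "mtr.tsv", sep="\t", index_col=0)
    dep = pd.read_csv(d / "dep.tsv", sep="\t", index_col=0)
    sites = pd.read_csv(d / "sites.tsv", sep="\t", index_col=0, dtype={"chrom": str})
    colonies = pd.read_csv(d / "colonies.tsv", sep="\t", index_col=0)
    return ReadCountSet(mtr, dep, sites, colonies)


def from_vcf(path, sample_ids: list[str] | None = None) -> ReadCountSet:  # pragma: no cover
    """Optional multi-sample VCF ingestion mapping AD fields to MTR/DEP.

    Kept import-light: cyvcf2 is only required when this entry point is
    actually used.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = sample_ids or list(vcf.samples)
    idx = [vcf.samples.index(s) for s in samples]
    recs, mtr_rows, dep_rows = [], [], []
    for i, v in enumerate(vcf):
        if len(v.REF) != 1 or len(v.ALT) != 1 or len(v.ALT[0]) != 1:
            pass  # indels kept too; AD still applies
        ad = v.format("AD")
        if ad is None:
            continue
        sid = f"s{i:07d}"
        recs.append(
            {
                "site_id": sid,
                "chrom": str(v.CHROM),
                "pos": int(v.POS),
                "ref": v.REF,
                "alt": v.ALT[0],
                "context": "",
                "gene": "",
                "consequence": "",
                "is_germline": False,
            }
        )
        mtr_rows.append([int(ad[j][1]) for j in idx])
        dep_rows.append([int(ad[j][0]) + int(ad[j][1]) for j in idx])
    sites = pd.DataFrame(recs).set_index("site_id")
    mtr = pd.DataFrame(mtr_rows, index=sites.index, columns=samples)
    dep = pd.DataFrame(dep_rows, index=sites.index, columns=samples)
    colonies = pd.DataFrame(index=pd.Index(samples, name="colony"))
    colonies["individual"] = "unknown"
    colonies["age_years"] = np.nan
    return ReadCountSet(mtr, dep, sites, colonies)
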