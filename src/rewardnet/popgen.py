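"""Candidate-SNP statistical genetics.

Covers the genetics stage of the pipeline: per-SNP call-rate QC,
Hardy-Weinberg goodness of fit, case-control genotypic/allelic association
with an allele odds ratio and Woolf confidence interval, EM-based pairwise
linkage disequilibrium (D, D', r-squared) from unphased genotypes, and the
additive imaging-genetics screen (main effect, gene x addiction interaction,
within-group effects) on a network-strength phenotype.

Genotypes are biallelic, stored as unordered two-character allele strings
("AG"); missing is "00".  Dosage codes count the designated risk allele
0/1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

MISSING = "00"


@dataclass(frozen=True)
class SNP:
    """Metadata for one biallelic marker.

    ``allele_a`` is the reference allele used for counting conventions
    (genotype counts are (n_AA, n_Aa, n_aa) relative to it); ``risk_allele``
    is the allele counted by the additive dosage code.
    """

    snp_id: str
    allele_a: str
    allele_b: str
    risk_allele: str = ""

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        risk = self.risk_allele or self.allele_b
        object.__setattr__(self, "risk_allele", risk)
        if risk not in (self.allele_a, self.allele_b):
            raise ValueError(f"{self.snp_id}: risk allele {risk!r} not among alleles")


@dataclass
class GenotypeTable:
    """Subjects x SNPs genotype calls with per-SNP metadata."""

    subjects: list[str]
    snps: list[SNP]
    calls: pd.DataFrame  # index subjects, columns snp ids, values "AG" / "00"

    def __post_init__(self) -> None:
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        if list(self.calls.index) != list(self.subjects):
            self.calls = self.calls.loc[self.subjects]
        if list(self.calls.columns) != ids:
            self.calls = self.calls[ids]
        for snp in self.snps:
            valid = {
                snp.allele_a + snp.allele_b, snp.allele_b + snp.allele_a,
                snp.allele_a * 2, snp.allele_b * 2, MISSING,
            }
            bad = set(self.calls[snp.snp_id]) - valid
            if bad:
                raise ValueError(f"{snp.snp_id}: invalid genotype codes {sorted(bad)}")

    def snp(self, snp_id: str) -> SNP:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s
        raise KeyError(f"unknown SNP {snp_id!r}")

    def call_rates(self) -> pd.Series:
        return (self.calls != MISSING).mean(axis=0)

    def dosage(self, snp_id: str) -> pd.Series:
        """Count of the risk allele per subject; NaN where missing."""
        snp = self.snp(snp_id)
        col = self.calls[snp_id]
        d = col.map(lambda g: np.nan if g == MISSING else g.count(snp.risk_allele))
        return d.astype(float)

    def genotype_counts(
        self, snp_id: str, subjects: list[str] | None = None
    ) -> tuple[int, int, int]:
        """(n_AA, n_Aa, n_aa) relative to ``allele_a``, missing excluded."""
        snp = self.snp(snp_id)
        col = self.calls[snp_id]
        if subjects is not None:
            col = col.loc[subjects]
        col = col[col != MISSING]
        n_a = col.map(lambda g: g.count(snp.allele_a))
        return (int((n_a == 2).sum()), int((n_a == 1).sum()), int((n_a == 0).sum()))


def call_rate_filter(
    table: GenotypeTable, min_rate: float = 0.98
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Drop SNPs whose call rate is not above ``min_rate``; report removals."""
    if not 0 < min_rate <= 1:
        raise ValueError("min_rate must be in (0, 1]")
    rates = table.call_rates()
    report = pd.DataFrame(
        {"snp": rates.index, "call_rate": rates.values,
         "kept": (rates > min_rate).values}
    )
    kept = [s for s in table.snps if rates[s.snp_id] > min_rate]
    filtered = GenotypeTable(
        subjects=table.subjects,
        snps=kept,
        calls=table.calls[[s.snp_id for s in kept]],
    )
    return filtered, report


def allele_frequencies(counts: tuple[int, int, int]) -> tuple[float, float]:
    """(freq_A, freq_a) from genotype counts (n_AA, n_Aa, n_aa)."""
    n_aa_, n_ab, n_bb = counts
    n = n_aa_ + n_ab + n_bb
    if n <= 0:
        raise ValueError("no genotyped subjects")
    freq_a = (2 * n_aa_ + n_ab) / (2 * n)
    return freq_a, 1.0 - freq_a


def hwe_chisq(counts: tuple[int, int, int]) -> tuple[float, float]:
    """Pearson goodness-of-fit chi-square (df 1) against HW proportions.

    Expected counts are (n p^2, 2 n p q, n q^2) with p the observed
    reference-allele frequency; no continuity correction.  Monomorphic
    markers (p in {0, 1}) are rejected — the test is undefined there.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative genotype count")
    n = c.sum()
    if n < 1:
        raise ValueError("empty genotype counts")
    p, q = allele_frequencies(tuple(int(x) for x in counts))
    if p == 0.0 or p == 1.0:
        raise ValueError("monomorphic SNP: HWE test undefined")
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    chi2 = float(((c - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class AssociationResult:
    """Case-control association of one SNP."""

    genotypic_chi2: float
    genotypic_p: float
    allelic_chi2: float
    allelic_p: float
    odds_ratio: float  # odds of allele A, cases over controls
    ci_lower: float
    ci_upper: float
    case_freq_a: float
    control_freq_a: float


def case_control_association(
    case_counts: tuple[int, int, int],
    control_counts: tuple[int, int, int],
    z: float = 1.959963984540054,
) -> AssociationResult:
    """Genotypic (df 2) and allelic (df 1) Pearson chi-square with allele OR.

    The allele table counts A as ``2 n_AA + n_Aa`` per group; the odds ratio
    is for allele A in cases over controls with a Woolf log-SE confidence
    interval at ``z`` (default two-sided 95%).  Zero margins are rejected
    rather than silently continuity-corrected.
    """
    geno = np.array([case_counts, control_counts], dtype=float)
    case_a = 2 * case_counts[0] + case_counts[1]
    case_b = case_counts[1] + 2 * case_counts[2]
    ctrl_a = 2 * control_counts[0] + control_counts[1]
    ctrl_b = control_counts[1] + 2 * control_counts[2]
    allele = np.array([[case_a, case_b], [ctrl_a, ctrl_b]], dtype=float)
    for tab, name in ((geno, "genotype"), (allele, "allele")):
        if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
            raise ValueError(f"zero marginal in the {name} table")
    g_chi2, g_p, _, _ = stats.chi2_contingency(geno, correction=False)
    a_chi2, a_p, _, _ = stats.chi2_contingency(allele, correction=False)
    if np.any(allele == 0):
        raise ValueError("zero allele cell: odds ratio undefined without correction")
    oratio = (case_a / case_b) / (ctrl_a / ctrl_b)
    log_se = np.sqrt(1 / case_a + 1 / case_b + 1 / ctrl_a + 1 / ctrl_b)
    lo = float(np.exp(np.log(oratio) - z * log_se))
    hi = float(np.exp(np.log(oratio) + z * log_se))
    return AssociationResult(
        genotypic_chi2=float(g_chi2), genotypic_p=float(g_p),
        allelic_chi2=float(a_chi2), allelic_p=float(a_p),
        odds_ratio=float(oratio), ci_lower=lo, ci_upper=hi,
        case_freq_a=case_a / (case_a + case_b),
        control_freq_a=ctrl_a / (ctrl_a + ctrl_b),
    )


@dataclass
class LDResult:
    snp_pair: tuple[str, str]
    d: float
    d_prime: float
    r_squared: float
    iterations: int
    log_likelihood: float
    haplotype_freqs: dict[str, float] = field(default_factory=dict)


def _em_haplotype_freqs(
    counts: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, int, list[float]]:
    """EM haplotype frequencies (fAB, fAb, faB, fab) from a 3x3 table.

    ``counts[i, j]`` is the number of subjects carrying i copies of allele A
    at the first SNP and j copies of allele B at the second (i, j in 2,1,0
    order).  Only double heterozygotes (i=j=1) have ambiguous phase: their
    two copies are either AB/ab or Ab/aB; EM splits them by the current
    relative likelihood of the two phase resolutions.
    """
    n = counts.sum()
    # unambiguous haplotype contributions: AB, Ab, aB, ab
    base = np.array([
        2 * counts[0, 0] + counts[0, 1] + counts[1, 0],
        2 * counts[0, 2] + counts[0, 1] + counts[1, 2],
        2 * counts[2, 0] + counts[2, 1] + counts[1, 0],
        2 * counts[2, 2] + counts[2, 1] + counts[1, 2],
    ], dtype=float)
    n_dh = counts[1, 1]
    p_a = (base[0] + base[1] + n_dh) / (2 * n)
    p_b = (base[0] + base[2] + n_dh) / (2 * n)
    f = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b,
                  (1 - p_a) * (1 - p_b)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    ll_trace: list[float] = []
    for it in range(1, max_iter + 1):
        cis = f[0] * f[3]      # AB/ab phase weight
        trans = f[1] * f[2]    # Ab/aB phase weight
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        expected = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        f_new = expected / (2 * n)
        ll_trace.append(_ld_log_likelihood(counts, f_new))
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            return f, it, ll_trace
    raise RuntimeError(
        f"EM did not converge within {max_iter} iterations (tol {tol})"
    )


def _ld_log_likelihood(counts: np.ndarray, f: np.ndarray) -> float:
    fab_, fAb, faB, fab = f[0], f[1], f[2], f[3]
    probs = np.array([
        [fab_**2, 2 * fab_ * fAb, fAb**2],
        [2 * fab_ * faB, 2 * (fab_ * fab + fAb * faB), 2 * fAb * fab],
        [faB**2, 2 * faB * fab, fab**2],
    ])
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    mask = counts > 0
    return float((counts[mask] * logp[mask]).sum())


def ld_pairwise(
    table: GenotypeTable,
    snp1: str,
    snp2: str,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LDResult:
    """Pairwise linkage disequilibrium from unphased genotypes via EM.

    Subjects missing either genotype are excluded pairwise.  D is the
    disequilibrium of the (allele_a of snp1, allele_a of snp2) haplotype;
    D' normalizes |D| by its maximum attainable value given the allele
    frequencies, and r-squared is D^2 / (pA qA pB qB).  At D = 0, D' is 0.
    """
    s1, s2 = table.snp(snp1), table.snp(snp2)
    calls = table.calls[[snp1, snp2]]
    calls = calls[(calls[snp1] != MISSING) & (calls[snp2] != MISSING)]
    if len(calls) == 0:
        raise ValueError("no subjects genotyped at both SNPs")
    i = calls[snp1].map(lambda g: g.count(s1.allele_a)).to_numpy()
    j = calls[snp2].map(lambda g: g.count(s2.allele_a)).to_numpy()
    counts = np.zeros((3, 3))
    for a, b in zip(i, j):
        counts[2 - a, 2 - b] += 1
    p_a = i.mean() / 2
    p_b = j.mean() / 2
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic SNP: LD undefined")
    f, iters, ll = _em_haplotype_freqs(counts, tol=tol, max_iter=max_iter)
    d = float(f[0] - p_a * p_b)
    q_a, q_b = 1 - p_a, 1 - p_b
    if d > 0:
        d_max = min(p_a * q_b, q_a * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, q_a * q_b)
    else:
        d_max = np.inf  # D' defined as 0 at D = 0
    d_prime = abs(d) / d_max if np.isfinite(d_max) else 0.0
    r2 = d * d / (p_a * q_a * p_b * q_b)
    hap_names = [
        s1.allele_a + s2.allele_a, s1.allele_a + s2.allele_b,
        s1.allele_b + s2.allele_a, s1.allele_b + s2.allele_b,
    ]
    return LDResult(
        snp_pair=(snp1, snp2), d=d, d_prime=float(d_prime),
        r_squared=float(r2), iterations=iters, log_likelihood=ll[-1],
        haplotype_freqs=dict(zip(hap_names, map(float, f))),
    )


@dataclass
class ScreenResult:
    """Additive-model screen of one SNP on a network phenotype."""

    snp_id: str
    main_beta: float
    main_p: float
    interaction_beta: float
    interaction_p: float
    case_beta: float
    case_p: float
    control_beta: float
    control_p: float


def _ols_term_p(y: pd.Series, X: pd.DataFrame, term: str) -> tuple[float, float]:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return float(model.params[term]), float(model.pvalues[term])


def snp_screen(
    phenotype: pd.Series,
    table: GenotypeTable,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    case_label: str = "HA",
    main_with_group: bool = False,
) -> list[ScreenResult]:
    """Per-SNP additive regression screen on a network-strength phenotype.

    Four Wald p-values per SNP: the pooled main effect from
    ``phenotype ~ dosage + covariates`` (optionally ``+ group``), the
    gene x addiction interaction from a model including both main effects,
    and within-group dosage effects fit separately per group.  Subjects with
    missing genotype are dropped per SNP; a stratum monomorphic for a SNP
    yields NaN for that stratum's test.
    """
    results = []
    groups = groups.loc[phenotype.index]
    g_ind = (groups == case_label).astype(float)
    covs = covariates.loc[phenotype.index] if covariates is not None else None
    for snp in table.snps:
        dose = table.dosage(snp.snp_id).loc[phenotype.index]
        ok = dose.notna() & phenotype.notna()
        y, d, g = phenotype[ok], dose[ok], g_ind[ok]
        cv = covs.loc[ok[ok].index] if covs is not None else None

        def design(cols: dict[str, pd.Series]) -> pd.DataFrame:
            X = pd.DataFrame(cols)
            if cv is not None:
                X = pd.concat([X, cv], axis=1)
            return X

        if d.nunique() < 2:
            results.append(ScreenResult(snp.snp_id, *([np.nan] * 8)))
            continue
        main_cols = {"dosage": d}
        if main_with_group:
            main_cols["group"] = g
        mb, mp = _ols_term_p(y, design(main_cols), "dosage")
        ib, ip = _ols_term_p(
            y, design({"dosage": d, "group": g, "dosage_x_group": d * g}),
            "dosage_x_group",
        )
        strata = {}
        for label, sel in (("case", g == 1), ("control", g == 0)):
            if sel.sum() > 2 and d[sel].nunique() >= 2:
                ycv = cv.loc[sel[sel].index] if cv is not None else None
                Xs = pd.DataFrame({"dosage": d[sel]})
                if ycv is not None:
                    Xs = pd.concat([Xs, ycv], axis=1)
                strata[label] = _ols_term_p(y[sel], Xs, "dosage")
            else:
                strata[label] = (np.nan, np.nan)
        results.append(ScreenResult(
            snp_id=snp.snp_id, main_beta=mb, main_p=mp,
            interaction_beta=ib, interaction_p=ip,
            case_beta=strata["case"][0], case_p=strata["case"][1],
            control_beta=strata["control"][0], control_p=strata["control"][1],
        ))
    return results
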