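"""Sloan neutral community model for occurrence-frequency data.

The model predicts how often a taxon should be detected across local
communities given only its mean relative abundance in the metacommunity and a
single free dispersal parameter Nm (local community size N times immigration
probability m).  Under neutral drift with immigration, a taxon at
metacommunity relative abundance p has local relative abundance distributed
Beta(Nm*p, Nm*(1-p)); with detection limit d (the smallest relative abundance
observable, by default one read out of the mean sample depth) its predicted
occurrence frequency is

    f(p) = P(local abundance > d) = 1 - I_d(Nm*p, Nm*(1-p))

where I is the regularized incomplete beta function.  Nm is estimated by
nonlinear least squares of observed occurrence frequencies on f(p).  Taxa
whose observed frequency falls above the 95% confidence band around the
neutral prediction are "above" (selected-for: more widespread than their
abundance warrants), below the band "below" (selected-against), and inside
"neutral".

The API follows the model/results convention: build a :class:`SloanNCM` from
arrays or an OTU table, call :meth:`~SloanNCM.fit`, inspect the returned
:class:`NCMResults`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.stats.proportion import proportion_confint

from .tables import DataError, OtuTable

__all__ = ["ncm_predict", "classify_frequencies", "SloanNCM", "NCMResults"]

_LOG10_NM_BOUNDS = (-2.0, 9.0)
_MULTISTART = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)  # log10 Nm starting points


def ncm_predict(p, Nm: float, d: float):
    """Predicted occurrence frequency for metacommunity abundance(s) `p`.

    Strictly increasing in p for fixed Nm and d.  `p` may be a scalar or
    array with entries in the open interval (0, 1).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise DataError("p must lie strictly between 0 and 1")
    if Nm <= 0:
        raise DataError("Nm must be positive")
    if not 0 < d < 1:
        raise DataError("detection limit d must lie in (0, 1)")
    # 1 - I_d(a, b) = upper tail of Beta(a, b) at the detection limit
    return 1.0 - special.betainc(Nm * p, Nm * (1.0 - p), d)


def classify_frequencies(f_obs, lower, upper):
    """Partition observed frequencies against a confidence band.

    Strictly above the band is "above", strictly below is "below"; equality
    with either bound counts as "neutral".
    """
    f_obs = np.asarray(f_obs, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    return np.where(f_obs > upper, "above", np.where(f_obs < lower, "below", "neutral"))


class SloanNCM:
    """Sloan neutral community model for (abundance, occurrence) pairs.

    Parameters
    ----------
    mean_abundance : array-like
        Per-taxon mean relative abundance p in the metacommunity, in (0, 1).
    occurrence_frequency : array-like
        Per-taxon observed occurrence frequency in [0, 1].
    n_samples : int
        Number of local communities over which frequencies were measured
        (sets the width of the confidence band).
    d : float
        Detection limit in relative-abundance units.
    taxon_ids, domain : optional
        Labels carried through to the per-OTU results table.
    """

    def __init__(
        self,
        mean_abundance,
        occurrence_frequency,
        n_samples: int,
        d: float,
        taxon_ids=None,
        domain=None,
    ):
        p = np.asarray(mean_abundance, dtype=float)
        f = np.asarray(occurrence_frequency, dtype=float)
        if p.shape != f.shape:
            raise DataError("abundance and frequency arrays differ in length")
        if np.any((p <= 0) | (p >= 1)):
            raise DataError("mean abundances must lie strictly in (0, 1)")
        if np.any((f < 0) | (f > 1)):
            raise DataError("occurrence frequencies must lie in [0, 1]")
        if p.size < 10:
            raise DataError("need at least 10 taxa to fit the model")
        if not 0 < d < 1:
            raise DataError("detection limit d must lie in (0, 1)")
        self.p = p
        self.f_obs = f
        self.n_samples = int(n_samples)
        self.d = float(d)
        self.taxon_ids = (
            list(taxon_ids) if taxon_ids is not None else [f"t{i}" for i in range(p.size)]
        )
        self.domain = list(domain) if domain is not None else None
        self.N = None  # community-size proxy, set by from_otu_table

    @classmethod
    def from_otu_table(cls, table: OtuTable, samples=None, d: float | None = None) -> "SloanNCM":
        """Build the model from an OTU table.

        `p` is each taxon's mean relative abundance over the chosen samples,
        the occurrence frequency its detection fraction, and the default
        detection limit 1/N with N the mean total reads per sample.
        """
        sub = table.subset_samples(samples) if samples is not None else table
        counts = sub.counts
        depths = counts.sum(axis=0)
        if (depths == 0).any():
            raise DataError("zero-depth sample in NCM input")
        rel = counts / depths
        p = rel.mean(axis=1)
        f_obs = (counts > 0).mean(axis=1)
        keep = (p > 0) & (p < 1)
        N = float(depths.mean())
        model = cls(
            p[keep].to_numpy(),
            f_obs[keep].to_numpy(),
            n_samples=counts.shape[1],
            d=(1.0 / N) if d is None else d,
            taxon_ids=list(p.index[keep]),
            domain=list(sub.domain.loc[p.index[keep]]),
        )
        model.N = N
        return model

    # -- fitting -----------------------------------------------------------
    def _sse(self, log10_nm: float) -> float:
        resid = self.f_obs - ncm_predict(self.p, 10.0 ** log10_nm, self.d)
        return float(resid @ resid)

    def fit(self, ci: float = 0.95) -> "NCMResults":
        """Estimate Nm by least squares and classify each taxon.

        The objective is optimized over log10(Nm) from several starting
        points (the surface is flat for extreme Nm); the best local optimum
        wins.  The confidence band is a Wilson score interval around each
        predicted frequency at the sample size of the fit.
        """
        if not 0 < ci < 1:
            raise DataError("ci must lie in (0, 1)")
        candidates = []
        scalar = optimize.minimize_scalar(
            self._sse, bounds=_LOG10_NM_BOUNDS, method="bounded",
            options={"xatol": 1e-10},
        )
        candidates.append((float(scalar.fun), float(scalar.x)))
        for x0 in _MULTISTART:
            local = optimize.minimize(
                lambda x: self._sse(x[0]), x0=[x0],
                bounds=[_LOG10_NM_BOUNDS], method="L-BFGS-B",
            )
            candidates.append((float(local.fun), float(local.x[0])))
        sse, log10_nm = min(candidates)
        if not np.isfinite(sse):
            raise DataError(f"NCM fit did not converge; final SSE {sse}")
        nm = 10.0 ** log10_nm

        f_pred = ncm_predict(self.p, nm, self.d)
        sst = float(((self.f_obs - self.f_obs.mean()) ** 2).sum())
        if sst == 0:
            r_squared, degenerate = float("nan"), True
        else:
            r_squared, degenerate = 1.0 - sse / sst, False

        lo, hi = proportion_confint(
            np.clip(f_pred * self.n_samples, 0, self.n_samples),
            self.n_samples,
            alpha=1 - ci,
            method="wilson",
        )
        otu_class = classify_frequencies(self.f_obs, lo, hi)
        per_otu = pd.DataFrame(
            {
                "p": self.p,
                "f_obs": self.f_obs,
                "f_pred": f_pred,
                "ci_lower": lo,
                "ci_upper": hi,
                "otu_class": otu_class,
            },
            index=pd.Index(self.taxon_ids, name="taxon_id"),
        )
        if self.domain is not None:
            per_otu["domain"] = self.domain
        return NCMResults(
            model=self,
            nm=nm,
            r_squared=r_squared,
            sse=sse,
            per_otu=per_otu,
            ci=ci,
            degenerate_sst=degenerate,
        )


class NCMResults:
    """Fit results: Nm, goodness of fit, and the per-OTU classification."""

    def __init__(self, model, nm, r_squared, sse, per_otu, ci, degenerate_sst):
        self.model = model
        self.nm = float(nm)
        self.r_squared = float(r_squared) if r_squared == r_squared else float("nan")
        self.sse = float(sse)
        self.per_otu = per_otu
        self.ci = ci
        self.degenerate_sst = degenerate_sst

    @property
    def m(self) -> float:
        """Migration probability Nm / N (requires a community-size proxy)."""
        if self.model.N is None:
            raise DataError("no community-size proxy N available on this fit")
        return self.nm / self.model.N

    def predict(self, p):
        return ncm_predict(p, self.nm, self.model.d)

    def class_summary(self, by_domain: bool = True) -> pd.DataFrame:
        """Percentages of OTUs per class (summing to 100), optionally per domain."""
        per = self.per_otu
        classes = ["neutral", "above", "below"]

        def _pct(frame):
            counts = frame["otu_class"].value_counts()
            total = len(frame)
            return pd.Series(
                {c: 100.0 * counts.get(c, 0) / total for c in classes}
            )

        if by_domain and "domain" in per.columns:
            return per.groupby("domain", group_keys=True).apply(_pct, include_groups=False)
        return _pct(per).to_frame("all").T

    def summary(self) -> str:
        n = len(self.per_otu)
        pct = self.class_summary(by_domain=False).iloc[0]
        lines = [
            "Sloan neutral community model",
            "=" * 46,
            f"taxa:                {n}",
            f"samples:             {self.model.n_samples}",
            f"detection limit d:   {self.model.d:.3e}",
            f"Nm:                  {self.nm:.4g}",
        ]
        if self.model.N is not None:
            lines.append(f"N (mean depth):      {self.model.N:.4g}")
            lines.append(f"m = Nm/N:            {self.m:.4g}")
        r2 = "undefined" if self.degenerate_sst else f"{self.r_squared:.4f}"
        lines += [
            f"R-squared:           {r2}",
            f"CI level:            {self.ci:.0%} (Wilson)",
            (
                f"classes:             neutral {pct['neutral']:.1f}% / "
                f"above {pct['above']:.1f}% / below {pct['below']:.1f}%"
            ),
        ]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "Nm": self.nm,
            "m": (self.nm / self.model.N) if self.model.N else None,
            "N": self.model.N,
            "d": self.model.d,
            "r_squared": None if self.degenerate_sst else self.r_squared,
            "n_samples": self.model.n_samples,
            "n_taxa": int(len(self.per_otu)),
        }
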