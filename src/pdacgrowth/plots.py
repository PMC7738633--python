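"""Optional diagnostic figures: fits, rate histograms, ROC, CCD, wasting bars.

The numeric report is the pipeline contract; these figures are convenience
mirrors of it, written only when requested.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cohort import Cohort, MM3_PER_CM3
from .classifier import ccd
from .growth import gompertz_volume


def plot_report(cohort: Cohort, fits: dict, report, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    # per-patient fits (first patient of each class, mirrors a fit panel)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, dclass in zip(axes, ("low", "high")):
        for p in cohort.by_class(dclass)[:1]:
            fit = fits.get(p.patient_id)
            if fit is None:
                continue
            t = p.times
            ax.plot(t, p.volumes_mm3 / MM3_PER_CM3, "o", label="observed")
            tt = np.linspace(t.min(), t.max(), 100)
            ax.plot(tt, gompertz_volume(tt, fit.params) / MM3_PER_CM3, "-",
                    label=f"fit (alpha={fit.alpha:.3f}/mo)")
            ax.set_title(f"{dclass} delta: {p.patient_id}")
            ax.set_xlabel("months since first scan")
            ax.set_ylabel("volume (cm$^3$)")
            ax.legend()
    fig.tight_layout()
    path = out / "gompertz_fits.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    table = report.fit_table
    fig, ax = plt.subplots(figsize=(5, 4))
    for dclass, color in (("low", "tab:blue"), ("high", "tab:red")):
        a = table[table.delta_class == dclass]["alpha"]
        ax.hist(a, bins=15, alpha=0.6, color=color, label=f"{dclass} delta")
    ax.set_xlabel("growth rate constant alpha (month$^{-1}$)")
    ax.set_ylabel("patients")
    ax.legend()
    fig.tight_layout()
    path = out / "alpha_distribution.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    clf = report.summary.get("classifier")
    if clf:
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        alphas = table["alpha"].to_numpy()
        from .classifier import fit_classifier
        model = fit_classifier(alphas, table["delta_class"].tolist())
        ax1.plot(model.roc_fpr, model.roc_tpr, "-o", ms=3)
        ax1.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax1.set_xlabel("false positive rate")
        ax1.set_ylabel("true positive rate")
        ax1.set_title(f"ROC (AUC={clf['auc']:.2f})")
        grid = np.linspace(alphas.min() * 0.5, alphas.max() * 1.1, 300)
        for dclass, color in (("low", "tab:blue"), ("high", "tab:red")):
            f = ccd(table[table.delta_class == dclass]["alpha"].to_numpy())
            ax2.step(grid, f(grid), color=color, label=f"{dclass} delta")
        ax2.axvline(clf["threshold"], color="k", ls=":", label="threshold")
        ax2.set_xlabel("alpha (month$^{-1}$)")
        ax2.set_ylabel("P(alpha > t)")
        ax2.legend()
        fig.tight_layout()
        path = out / "classification.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    rates = report.wasting_rates
    if not rates.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        tissues = sorted(rates["tissue"].unique())
        width = 0.35
        xs = np.arange(len(tissues))
        for off, (dclass, color) in zip(
            (-width / 2, width / 2), (("low", "tab:blue"), ("high", "tab:red"))
        ):
            means = [
                rates[(rates.tissue == t) & (rates.delta_class == dclass)][
                    "rate_pct_per_month"
                ].mean()
                for t in tissues
            ]
            ax.bar(xs + off, means, width, color=color, label=f"{dclass} delta")
        ax.set_xticks(xs, tissues)
        ax.set_ylabel("wasting rate (%/month)")
        ax.axhline(0, color="k", lw=0.8)
        ax.legend()
        fig.tight_layout()
        path = out / "wasting_rates.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    return written
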