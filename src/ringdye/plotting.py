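"""Optional static figures (matplotlib imported lazily)."""

from __future__ import annotations

__all__ = ["plot_spectra", "plot_transfer_distribution"]


def plot_spectra(results, ax=None):
    """Complex vs component-sum absorption spectra with the stick spectrum."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    spectra = results.spectra()
    lam = spectra["complex"].wavelengths
    scale = spectra["complex"].absorbance.max()
    ax.plot(lam, spectra["complex"].absorbance / scale, "k-", label="complex")
    ax.plot(lam, spectra["ring"].absorbance / scale, "r-", lw=1, label="ring")
    ax.plot(lam, spectra["dye"].absorbance / scale, "-", color="purple", lw=1, label="dye")
    ax.plot(
        lam,
        (spectra["ring"].absorbance + spectra["dye"].absorbance) / scale,
        "--", color="gray", label="ring + dye",
    )
    sticks = spectra["complex"].sticks
    smax = sticks[:, 1].max() or 1.0
    ax.vlines(sticks[:, 0], 0, sticks[:, 1] / smax, color="0.4", lw=1)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("absorbance (a.u.)")
    ax.legend(frameon=False)
    return ax


def plot_transfer_distribution(dist, ax=None, bins=60):
    """Histogram of ensemble transfer times with the 50 ps marker."""
    import numpy as np
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    finite = dist.samples[np.isfinite(dist.samples)]
    ax.hist(finite, bins=bins, color="steelblue", edgecolor="none")
    ax.axvline(50.0, color="k", ls="--", lw=1)
    ax.set_xlabel("transfer time (ps)")
    ax.set_ylabel("count")
    ax.set_title(f"median {dist.median:.2f} ps, P(<50 ps) = {dist.prob_within(50):.4f}")
    return ax
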