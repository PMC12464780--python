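"""Convenience plots over report tables (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .datatypes import Isotherm, LateralPressureProfile


def plot_isotherms(isotherms: list[Isotherm], path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for iso in isotherms:
        ax.plot(iso.area, iso.pressure, label=iso.label or None)
    ax.set_xlabel("molecular area (Å$^2$)")
    ax.set_ylabel("surface pressure (mN/m)")
    if any(iso.label for iso in isotherms):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_lpp(profile: LateralPressureProfile, path,
             bounds: tuple[float, float] | None = None) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(profile.z, profile.lpp)
    ax.axhline(0.0, color="k", lw=0.5)
    if bounds is not None:
        for b in bounds:
            ax.axvline(b, color="r", ls="--", lw=0.8)
    ax.set_xlabel("z (nm)")
    ax.set_ylabel("lateral pressure (bar)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
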