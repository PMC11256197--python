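"""Dose-response curve plots from an assembled analysis report."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

_ARM_STYLE = {"CONV": dict(color="#d4527f", marker="D"), "FLASH": dict(color="#3b6fb6", marker="s")}


def plot_dose_response(report: dict, assay: str, out_dir: str | Path) -> list[Path]:
    """One figure per grade: observed responder fractions plus fitted curves."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dose_lattice = report["curves"]["dose_Gy"]
    paths = []
    for key, block in report["fits"].get(assay, {}).items():
        fig, ax = plt.subplots(figsize=(5, 4))
        for arm in ("CONV", "FLASH"):
            style = _ARM_STYLE[arm]
            obs = block[arm]["observed"]
            frac = [r / n if n else float("nan") for r, n in zip(obs["responders"], obs["n"])]
            ax.plot(obs["dose"], frac, linestyle="none", label=f"{arm} observed", **style)
            curve = report["curves"][assay].get(key, {}).get(arm)
            if curve is not None:
                ax.plot(dose_lattice, curve, color=style["color"], label=f"{arm} fit")
        ax.set_xlabel("Dose (Gy)")
        ax.set_ylabel(f"P(grade ≥ {key})")
        ax.set_ylim(-0.05, 1.05)
        ax.set_title(f"{assay} toxicity, grade {key}")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out_dir / f"dose_response_{assay}_grade_{key.replace('.', '_')}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
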