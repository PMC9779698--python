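"""Z-score normalization of individual feature vectors against packaged
norms, and the lab-report style visualization.

Two normalizations are provided. The raw z-score measures distance to the
normative mean in SDs:

    z_raw = (x - mean) / sd

For parameters with a generalizable confound association (identified by the
cross-validation gate), the residual z-score standardizes the residual from
the covariate-adjusted normative regression instead:

    eps = x - (b0 + bAge*age + bSex*sex + bHeight*height + bWeight*weight)
    z_res = eps / s_eps

with s_eps the residual SD of the normative fit; the study term is never
used for prediction. Where a model exists, z_res is the preferred score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path

import numpy as np

from .cohort import NormativeEntry
from .confounds import Coefficient, ConfoundModel
from .parameters import PARAMETER_INDEX
from .types import FeatureVector, Subject

RESOURCE_VERSION = 1


@dataclass
class NormativeResource:
    """Per-parameter normative statistics plus confound models for the
    gated parameters; everything needed to score a new subject."""

    entries: dict[str, NormativeEntry]
    models: dict[str, ConfoundModel] = field(default_factory=dict)
    provenance: str = "user-cohort"
    version: int = RESOURCE_VERSION

    def __post_init__(self) -> None:
        for key in self.models:
            if key not in self.entries:
                raise ValueError(f"gated parameter {key!r} lacks a normative entry")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = {"version": self.version, "provenance": self.provenance,
               "parameters": {}}
        for key, e in self.entries.items():
            blob: dict = {
                "n": e.n, "mean": e.mean, "sd": e.sd, "cov": e.cov,
                "q1": e.q1, "q3": e.q3,
            }
            if e.rtest2 is not None:
                blob["mean_rtest2"] = e.rtest2
            if key in self.models:
                m = self.models[key]
                blob["model"] = {
                    "residual_sd": m.residual_sd,
                    "n": m.n,
                    "coefficients": {
                        name: {"estimate": c.estimate, "ci": [c.ci_low, c.ci_high],
                               "p": c.p_value}
                        for name, c in m.coefficients.items()
                    },
                }
            out["parameters"][key] = blob
        return out

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        return path

    @classmethod
    def from_dict(cls, blob: dict) -> "NormativeResource":
        entries: dict[str, NormativeEntry] = {}
        models: dict[str, ConfoundModel] = {}
        for key, b in blob["parameters"].items():
            entries[key] = NormativeEntry(
                parameter=key, n=int(b["n"]), mean=float(b["mean"]),
                sd=float(b["sd"]), cov=float(b["cov"]),
                q1=float(b["q1"]), q3=float(b["q3"]),
                rtest2=b.get("mean_rtest2"),
            )
            if "model" in b:
                mb = b["model"]
                coeffs = {
                    name: Coefficient(
                        estimate=float(c["estimate"]),
                        ci_low=float(c["ci"][0]), ci_high=float(c["ci"][1]),
                        p_value=float(c["p"]),
                    )
                    for name, c in mb["coefficients"].items()
                }
                models[key] = ConfoundModel(
                    parameter=key, coefficients=coeffs,
                    residual_sd=float(mb["residual_sd"]), n=int(mb["n"]),
                )
        return cls(entries=entries, models=models,
                   provenance=blob.get("provenance", "unknown"),
                   version=int(blob.get("version", RESOURCE_VERSION)))

    @classmethod
    def load(cls, path: str | Path) -> "NormativeResource":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


_reference_cache: NormativeResource | None = None


def load_reference_resource() -> NormativeResource:
    """The packaged normative resource: reference values for healthy adults
    aged 20-60 (n = 133, three pooled studies) recorded with a single RGB-D
    camera at 1.5-4.5 m, as published for this class of system. Step length
    and step width of the comfortable-speed walk carry confound models; all
    other parameters are scored with z_raw only."""
    global _reference_cache
    if _reference_cache is None:
        ref = importlib_resources.files("motornorms.resources") / "reference_norms.json"
        _reference_cache = NormativeResource.from_dict(
            json.loads(ref.read_text())
        )
    return _reference_cache


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def z_raw_score(x: float, entry: NormativeEntry) -> float:
    """Raw z-score: (x - normative mean) / normative SD."""
    if entry.sd <= 0:
        raise ValueError("z_raw undefined for zero normative SD")
    return (x - entry.mean) / entry.sd


def residual(x: float, subject: Subject, model: ConfoundModel) -> float:
    """Residual of x from the covariate-adjusted normative prediction."""
    return x - model.predict(subject)


def z_res_score(x: float, subject: Subject, model: ConfoundModel) -> float:
    """Residual z-score: residual divided by the normative residual SD."""
    return residual(x, subject, model) / model.residual_sd


@dataclass
class ZEntry:
    parameter: str
    value: float
    z_raw: float
    z_res: float | None = None
    residual: float | None = None

    @property
    def preferred(self) -> float:
        """z_res where a confound model exists, z_raw otherwise."""
        return self.z_raw if self.z_res is None else self.z_res


@dataclass
class ZProfile:
    subject: Subject
    entries: dict[str, ZEntry]
    skipped: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


def score_subject(
    features: FeatureVector | dict,
    subject: Subject,
    norms: NormativeResource,
) -> ZProfile:
    """Score one subject's feature vector against a normative resource.

    Every parameter present in both the features and the norms gets a
    z_raw; parameters with a confound model additionally get a z_res (the
    preferred score). Parameters missing from the norms are skipped with a
    recorded warning reason.
    """
    entries: dict[str, ZEntry] = {}
    skipped: dict[str, str] = {}
    if isinstance(features, FeatureVector):
        values = features.present_items()
    else:
        values = {k: v for k, v in features.items() if v is not None and np.isfinite(v)}
    for key, x in values.items():
        if key not in norms.entries:
            skipped[key] = "parameter absent from norms"
            continue
        entry = norms.entries[key]
        if entry.sd <= 0:
            skipped[key] = "zero normative SD"
            continue
        ze = ZEntry(parameter=key, value=float(x),
                    z_raw=z_raw_score(x, entry))
        if key in norms.models:
            m = norms.models[key]
            ze.residual = residual(x, subject, m)
            ze.z_res = ze.residual / m.residual_sd
        entries[key] = ze
    return ZProfile(subject=subject, entries=entries, skipped=skipped)


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


def render_report(profile: ZProfile, out: str | Path, title: str | None = None):
    """Render a lab-report style z-score chart (one marker row per
    parameter, grouped by task, guides at z = 0, +-1, +-2; both z_raw and
    z_res shown where available). Displayed values are rounded to 2
    decimals. Deterministic layout; returns the output path."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not profile.entries:
        raise ValueError("cannot render an empty z-profile")

    keys = [k for k in PARAMETER_INDEX if k in profile.entries]
    n = len(keys)
    fig, ax = plt.subplots(figsize=(7.5, 0.28 * n + 1.8))
    for g, style in ((0, "-"), (1, "--"), (-1, "--"), (2, ":"), (-2, ":")):
        ax.axvline(g, color="0.6" if g else "0.3", linestyle=style, lw=0.9, zorder=0)

    ytick, ylab = [], []
    last_task = None
    y = 0
    for key in keys:
        pdef = PARAMETER_INDEX[key]
        if pdef.task != last_task:
            last_task = pdef.task
            y -= 1
            ytick.append(y)
            ylab.append(f"— {pdef.task.value} —")
        y -= 1
        ze = profile.entries[key]
        ax.plot(round(ze.z_raw, 2), y, "o", color="tab:blue", ms=5,
                label="z_raw" if "z_raw" not in ax.get_legend_handles_labels()[1] else None)
        if ze.z_res is not None:
            ax.plot(round(ze.z_res, 2), y, "s", color="tab:red", ms=5,
                    label="z_res" if "z_res" not in ax.get_legend_handles_labels()[1] else None)
        ytick.append(y)
        ylab.append(f"{pdef.label} [{pdef.unit}]")
    ax.set_yticks(ytick)
    ax.set_yticklabels(ylab, fontsize=7)
    ax.set_xlabel("z-score")
    lim = max(3.0, max(abs(z.preferred) for z in profile.entries.values()) + 0.5)
    ax.set_xlim(-lim, lim)
    ax.set_title(title or f"Motor-capacity z-profile: {profile.subject.subject_id}")
    ax.legend(loc="lower right", fontsize=7)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
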