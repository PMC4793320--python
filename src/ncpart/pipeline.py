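"""End-to-end orchestration: clean -> NC -> PART -> congruence -> confirm -> key.

Every run writes its artifacts plus a machine-readable manifest carrying the
seed and a hash of the configuration, so identical configurations reproduce
byte-identical JSON artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import default_multivariate_traits
from .confirm import WILDCARD, loocv_lda, wildcard_assign
from .errors import NCPartError, NumericError, ValidationError
from .gap import congruence, part
from .io import correlation_screen, derive_cs, read_morpho_table, write_morpho_table
from .mra import best_ratio_search, ratio_pair_power
from .nc import build_dendrogram, centroid_distances, fit_group_lda, nest_centroids, to_newick

__all__ = ["RunConfig", "StageError", "run_pipeline", "STAGES"]

STAGES = ("clean", "nc", "part-hclust", "part-kmeans", "congruence", "confirm", "key")


@dataclass
class RunConfig:
    input: str
    out: str
    dialect: str = "csv"
    seed: int = 0
    include_traits: list[str] = field(default_factory=list)
    exclude_traits: list[str] = field(default_factory=list)
    linkage: str = "ward"
    kmax: int = 15
    min_size: int = 8
    B: int = 1000
    clusterers: list[str] = field(default_factory=lambda: ["hclust", "kmeans"])
    priors: str = "equal"
    screen_threshold: float = 0.2
    ridge: float = 0.0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat key=value config file; explicit overrides win."""
        values: dict[str, object] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"bad config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = val
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls._coerce(values)

    @classmethod
    def _coerce(cls, values: dict) -> "RunConfig":
        fields = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(values) - fields
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        out = dict(values)
        for key in ("seed", "kmax", "min_size", "B"):
            if key in out:
                out[key] = int(out[key])
        for key in ("screen_threshold", "ridge"):
            if key in out:
                out[key] = float(out[key])
        for key in ("include_traits", "exclude_traits", "clusterers"):
            if key in out and isinstance(out[key], str):
                out[key] = [s for s in out[key].replace(",", " ").split() if s]
        return cls(**out)

    def config_hash(self) -> str:
        """Hash of everything that affects results (the output path does not)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class StageError(NCPartError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def _json_write(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def _stamp(path: Path, config: RunConfig) -> None:
    """Embed config hash and seed into an already-written JSON artifact."""
    payload = json.loads(path.read_text())
    if isinstance(payload, list):
        payload = {"entries": payload}
    payload.update({"config_hash": config.config_hash(), "seed": config.seed})
    _json_write(path, payload)


def run_pipeline(config: RunConfig, through: str = "key") -> Path:
    """Execute the protocol up to ``through`` and return the run directory."""
    if through not in ("clean", "nc", "part", "congruence", "confirm", "key"):
        raise ValidationError(f"unknown stage {through!r}")
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    def record(stage: str, artifacts: list[str], **info) -> None:
        manifest["stages"][stage] = {"artifacts": artifacts, **info}
        _json_write(out / "manifest.json", manifest)

    # ---- clean -----------------------------------------------------------
    try:
        table = read_morpho_table(config.input, config.dialect)
        table = derive_cs(table)
        report = correlation_screen(table, threshold=config.screen_threshold)
        flagged = report.flagged
        if config.include_traits:
            analysis_traits = [t for t in config.include_traits
                               if t in table.trait_columns]
        else:
            analysis_traits = default_multivariate_traits(
                available=tuple(table.trait_columns),
                exclude=tuple(["PPL", *flagged, *config.exclude_traits]))
        complete = [t for t in analysis_traits if table.data[t].notna().all()]
        if len(complete) < 2:
            raise ValidationError("fewer than 2 complete analysis traits remain")
        write_morpho_table(table, out / "cleaned.csv")
        report.to_json(out / "correlation_report.json")
        _stamp(out / "correlation_report.json", config)
        record("clean", ["cleaned.csv", "correlation_report.json"],
               n_specimens=len(table), n_nests=int(table.nest_ids.nunique()),
               analysis_traits=complete, flagged=flagged)
    except NCPartError as exc:
        raise StageError("clean", exc) from exc
    if through == "clean":
        return out

    # ---- nc --------------------------------------------------------------
    try:
        proj = fit_group_lda(table, traits=complete, ridge=config.ridge)
        cents = nest_centroids(proj)
        dists = centroid_distances(cents)
        dend = build_dendrogram(dists, config.linkage)
        proj.scores.rename_axis("specimen_id").to_csv(out / "lda_scores.csv",
                                                      float_format="%.17g")
        cents.centroids.rename_axis("nest_id").to_csv(out / "nest_centroids.csv",
                                                      float_format="%.17g")
        dists.write_csv(out / "distances.csv")
        (out / "dendrogram.nwk").write_text(to_newick(dend) + "\n")
        record("nc", ["lda_scores.csv", "nest_centroids.csv", "distances.csv",
                      "dendrogram.nwk"],
               axis_count=proj.axis_count, linkage=config.linkage)
    except NCPartError as exc:
        raise StageError("nc", exc) from exc
    if through == "nc":
        return out

    # ---- part ------------------------------------------------------------
    partitions = {}
    nest_ids = list(cents.centroids.index.astype(str))
    coords = cents.centroids.to_numpy(float)
    for i, clusterer in enumerate(config.clusterers):
        stage = f"part-{clusterer}"
        try:
            rng = np.random.default_rng([config.seed, i])
            p = part(coords, ids=nest_ids, kmax=config.kmax,
                     min_size=config.min_size, B=config.B, clusterer=clusterer,
                     rng=rng, linkage=config.linkage)
            p.write_csv(out / f"partition_{clusterer}.csv")
            _json_write(out / f"gap_{clusterer}.json", p.trace)
            _stamp(out / f"gap_{clusterer}.json", config)
            partitions[clusterer] = p
            record(stage, [f"partition_{clusterer}.csv", f"gap_{clusterer}.json"],
                   n_clusters=p.n_clusters,
                   n_outliers=sum(1 for l in p.labels if l == "OUTLIER"))
        except NCPartError as exc:
            raise StageError(stage, exc) from exc
    if through == "part":
        return out

    # ---- congruence ------------------------------------------------------
    try:
        plist = list(partitions.values())
        if len(plist) >= 2:
            cong = congruence(plist[0], plist[1])
        else:
            p = plist[0]
            cong_ids = [i for i, l in zip(p.ids, p.labels) if l != "OUTLIER"]
            from .gap import CongruenceSet
            cong = CongruenceSet(cong_ids,
                                 [i for i in p.ids if i not in cong_ids], {})
        cong.to_json(out / "congruence.json")
        _stamp(out / "congruence.json", config)
        record("congruence", ["congruence.json"],
               n_congruent=len(cong.congruent_ids),
               n_wildcard=len(cong.wildcard_ids))
    except NCPartError as exc:
        raise StageError("congruence", exc) from exc
    if through == "congruence":
        return out

    # ---- confirm ---------------------------------------------------------
    try:
        ref = plist[0].as_series()
        nest_label = {nid: f"C{lab}" for nid, lab in ref.items() if lab != "OUTLIER"}
        congruent_nests = set(cong.congruent_ids)
        imposed = pd.Series(
            [nest_label[n] if n in congruent_nests else WILDCARD
             for n in table.nest_ids.astype(str)],
            index=table.data.index, dtype=object)
        X = table.traits(complete)
        if (imposed == WILDCARD).any():
            result = wildcard_assign(X, imposed, priors=config.priors,
                                     ridge=config.ridge)
        else:
            result = loocv_lda(X, imposed, priors=config.priors,
                               ridge=config.ridge)
        result.to_json(out / "classification.json")
        _stamp(out / "classification.json", config)
        result.confusion_with_percent().rename_axis("class").to_csv(
            out / "confusion.csv")
        final = imposed.copy()
        for sid in result.wildcard_predictions.index:
            final[sid] = result.wildcard_predictions[sid]
        final.rename("final_class").rename_axis("specimen_id").to_csv(
            out / "final_labels.csv")
        record("confirm", ["classification.json", "confusion.csv",
                           "final_labels.csv"],
               overall_percent=result.overall_percent,
               n_classes=len(result.classes),
               n_wildcards=int((imposed == WILDCARD).sum()))
    except NCPartError as exc:
        raise StageError("confirm", exc) from exc
    if through == "confirm":
        return out

    # ---- key -------------------------------------------------------------
    try:
        classes = sorted(final.unique())
        couplets = []
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                mask = final.isin([a, b])
                sub = X.loc[mask]
                labs = final[mask]
                ranked = best_ratio_search(sub, labs, complete)
                top = ranked[0]
                entry = {"classes": [a, b], "best_ratio": top.to_dict()}
                if len(ranked) > 1:
                    second = next((r for r in ranked[1:]
                                   if {r.numerator, r.denominator}
                                   != {top.numerator, top.denominator}), None)
                    if second is not None:
                        pair = ratio_pair_power(
                            sub, labs, (top.numerator, top.denominator),
                            (second.numerator, second.denominator))
                        entry["best_pair"] = pair.to_dict()
                couplets.append(entry)
        _json_write(out / "key_report.json",
                    {"couplets": couplets,
                     "config_hash": config.config_hash(), "seed": config.seed})
        lines = []
        for c in couplets:
            a, b = c["classes"]
            r = c["best_ratio"]
            lines.append(f"{a} vs {b}: {r['ratio']} "
                         f"({r['percent_correct']:.1f}%)")
            if "best_pair" in c:
                p = c["best_pair"]
                lines.append(f"  pair {p['ratios'][0]} + {p['ratios'][1]} "
                             f"({p['percent_correct']:.1f}%)")
        (out / "key.txt").write_text("\n".join(lines) + "\n")
        record("key", ["key_report.json", "key.txt"], n_couplets=len(couplets))
    except NCPartError as exc:
        raise StageError("key", exc) from exc
    return out
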