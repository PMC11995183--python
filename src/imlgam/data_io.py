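"""File I/O for expression matrices, clinical tables, gene lists and model bundles.

Expression files are tab-separated with genes in rows and samples in columns
(first column = gene identifier, header row = sample identifiers). Clinical
tables are comma-separated with columns ``sample_id,response,cancer_type``
and optional ``os_time,os_event``. Response labels follow RECIST: CR/PR are
responders, SD/PD non-responders.

A trained model is persisted as a *bundle directory*: a human-readable
``manifest.json`` (gene pairs, learner grid, stacked coefficients, threshold,
training metadata) plus one opaque fitted-learner artifact per grid member —
forest and kernel learners have no compact plain-text form.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BUNDLE_FORMAT_VERSION = "1"

RESPONDER_LABELS = {"CR", "PR"}
NONRESPONDER_LABELS = {"SD", "PD"}


@dataclass
class ExpressionMatrix:
    """Bulk expression, genes x samples, in any rank-preserving units.

    Only within-sample orderings are consumed downstream, so counts, TPM or
    log-scale values are all acceptable and never rescaled here.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {name} IDs: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations aligned with an expression matrix.

    ``response`` is binary (1 = responder), ``cancer_type`` is a mandatory
    adjustment covariate, and overall survival (months + event flag) is
    optional.
    """

    sample_ids: list[str]
    response: np.ndarray  # {0,1}
    cancer_type: list[str]
    os_time: np.ndarray | None = None
    os_event: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=int)
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise ValueError(f"duplicate sample IDs: {sorted(dupes)}")
        n = len(self.sample_ids)
        if self.response.shape != (n,) or len(self.cancer_type) != n:
            raise ValueError("clinical columns have inconsistent lengths")
        if not set(np.unique(self.response)) <= {0, 1}:
            raise ValueError("response must be binary 0/1")
        if any(not str(c).strip() for c in self.cancer_type):
            raise ValueError("cancer_type must be non-empty for every sample")
        if self.os_event is not None and self.os_time is None:
            raise ValueError("os_event present without os_time")
        if self.os_time is not None:
            self.os_time = np.asarray(self.os_time, dtype=float)
            if np.any(self.os_time < 0):
                raise ValueError("os_time must be non-negative")
            if self.os_event is not None:
                self.os_event = np.asarray(self.os_event, dtype=int)
                if not set(np.unique(self.os_event)) <= {0, 1}:
                    raise ValueError("os_event must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def reorder(self, sample_ids: list[str]) -> "ClinicalTable":
        """Return a copy aligned to the given sample order (must be a subset)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples absent from clinical table: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return ClinicalTable(
            sample_ids=list(sample_ids),
            response=self.response[idx],
            cancer_type=[self.cancer_type[i] for i in idx],
            os_time=None if self.os_time is None else self.os_time[idx],
            os_event=None if self.os_event is None else self.os_event[idx],
        )


def _duplicates(ids: list[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in ids:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def map_response(label: str | int | float) -> int:
    """Map a RECIST label (or an already-binary flag) to 1=responder / 0=non.

    CR and PR are responders; SD and PD are non-responders; "1"/"0" (or the
    integers) pass through unchanged. Anything else is rejected.
    """
    s = str(label).strip().upper()
    if s in RESPONDER_LABELS:
        return 1
    if s in NONRESPONDER_LABELS:
        return 0
    if s in {"1", "1.0"}:
        return 1
    if s in {"0", "0.0"}:
        return 0
    raise ValueError(
        f"unrecognized response label {label!r}; accepted: CR, PR, SD, PD, 1, 0"
    )


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene IDs, header = samples)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no sample columns found")
    dupes = _duplicates(list(df.index))
    if dupes:
        raise ValueError(f"{path}: duplicate gene IDs: {sorted(dupes)}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at gene {gene!r}, "
                f"sample {col!r}"
            ) from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical CSV; samples with missing response are dropped (logged)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "response", "cancer_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns: {sorted(missing)}")
    na_resp = df["response"].isna() | (df["response"].str.strip() == "")
    if na_resp.any():
        logger.info("dropping %d samples with missing response", int(na_resp.sum()))
        df = df[~na_resp]
    if df["cancer_type"].isna().any() or (df["cancer_type"].str.strip() == "").any():
        bad = df.loc[
            df["cancer_type"].isna() | (df["cancer_type"].str.strip() == ""),
            "sample_id",
        ]
        raise ValueError(
            f"{path}: missing cancer_type for samples {list(bad.head())} — the "
            "cancer-type adjustment covariate is mandatory"
        )
    response = np.array([map_response(v) for v in df["response"]])
    os_time = os_event = None
    if "os_time" in df.columns:
        os_time = pd.to_numeric(df["os_time"], errors="raise").to_numpy(dtype=float)
        if "os_event" in df.columns:
            os_event = pd.to_numeric(df["os_event"], errors="raise").to_numpy(dtype=int)
    elif "os_event" in df.columns:
        raise ValueError(f"{path}: os_event present without os_time")
    return ClinicalTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        response=response,
        cancer_type=[str(c) for c in df["cancer_type"]],
        os_time=os_time,
        os_event=os_event,
    )


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    data = {
        "sample_id": clin.sample_ids,
        "response": clin.response,
        "cancer_type": clin.cancer_type,
    }
    if clin.os_time is not None:
        data["os_time"] = clin.os_time
        if clin.os_event is not None:
            data["os_event"] = clin.os_event
    pd.DataFrame(data).to_csv(path, index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a gene list, one symbol per line; blank lines and '#' comments skipped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes: list[str] = []
    seen: set[str] = set()
    for line in path.read_text().splitlines():
        g = line.strip()
        if not g or g.startswith("#"):
            continue
        if g not in seen:
            genes.append(g)
            seen.add(g)
    if not genes:
        raise ValueError(f"{path}: gene list is empty")
    return genes


# ---------------------------------------------------------------------------
# Model bundle persistence
# ---------------------------------------------------------------------------

def save_model(model, out_dir: str | Path) -> Path:
    """Persist a trained model as manifest.json + one artifact per learner.

    Returns the bundle directory. ``load_model(save_model(m))`` reproduces
    scores bit-identically.
    """
    from .ensemble import IMLGAMModel  # local import avoids a cycle

    if not isinstance(model, IMLGAMModel):
        raise TypeError("save_model expects a trained IMLGAMModel")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "pairs": [[p.gene_a, p.gene_b] for p in model.pairs],
        "grid": [
            {"id": c.id, "family": c.family, "hyperparameters": c.hyperparameters}
            for c in model.grid
        ],
        "chromosome": [int(b) for b in model.chromosome],
        "stacked": {
            "member_ids": list(model.stacked.member_ids),
            "intercept": float(model.stacked.intercept),
            "coefficients": {k: float(v) for k, v in model.stacked.coefficients.items()},
        },
        "threshold": float(model.threshold),
        "orientation": model.orientation,
        "metadata": model.metadata,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for cfg in model.grid:
        joblib.dump(model.full_fits[cfg.id], out_dir / f"{cfg.id}.joblib")
    return out_dir


def load_model(bundle_dir: str | Path):
    """Load a bundle written by save_model, validating version and blobs."""
    from .ensemble import IMLGAMModel, StackedModel
    from .learners import LearnerConfig
    from .pairs import GenePair

    bundle_dir = Path(bundle_dir)
    manifest_path = bundle_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {bundle_dir}")
    manifest = json.loads(manifest_path.read_text())
    version = manifest.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"incompatible bundle format version {version!r}; "
            f"this build reads version {BUNDLE_FORMAT_VERSION!r}"
        )
    grid = [
        LearnerConfig(id=c["id"], family=c["family"], hyperparameters=c["hyperparameters"])
        for c in manifest["grid"]
    ]
    grid_ids = {c.id for c in grid}
    stacked_raw = manifest["stacked"]
    unknown = set(stacked_raw["coefficients"]) - grid_ids
    if unknown:
        raise ValueError(f"stacked coefficients reference unknown learners: {sorted(unknown)}")
    full_fits = {}
    for cfg in grid:
        blob = bundle_dir / f"{cfg.id}.joblib"
        if not blob.exists():
            raise FileNotFoundError(f"bundle is missing learner artifact for {cfg.id!r}")
        full_fits[cfg.id] = joblib.load(blob)
    pairs = [GenePair(a, b) for a, b in manifest["pairs"]]
    stacked = StackedModel(
        member_ids=list(stacked_raw["member_ids"]),
        intercept=float(stacked_raw["intercept"]),
        coefficients={k: float(v) for k, v in stacked_raw["coefficients"].items()},
    )
    threshold = float(manifest["threshold"])
    if not np.isfinite(threshold):
        raise ValueError("bundle threshold is not finite")
    return IMLGAMModel(
        pairs=pairs,
        grid=grid,
        full_fits=full_fits,
        chromosome=np.array(manifest["chromosome"], dtype=int),
        stacked=stacked,
        threshold=threshold,
        orientation=manifest["orientation"],
        metadata=manifest.get("metadata", {}),
    )
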