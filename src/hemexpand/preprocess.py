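"""Clinical feature-matrix preprocessing.

Implements the cleaning pipeline for long-format event tables: hourly
resampling (last observation per half-open hour bin, presence flags for
medications), one-hot encoding, hard physiologic-range removal, 3-SD
winsorization to the 2.5th/97.5th training percentiles, and tiered
missing-value imputation (median/mode below 5% missing, patient-level KNN
between 5% and 20%, drop above 20% unless whitelisted).

All reference statistics — medians, modes, SDs, percentiles, KNN neighbours
— are computed on the training split at ``fit`` time and frozen, so
validation and test transforms cannot leak. Every removal, winsorization,
drop and imputation is recorded in an audit log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .schema import DEFAULT_SCHEMA, FeatureDef

__all__ = [
    "FeatureMatrix",
    "resample_hourly",
    "one_hot",
    "PreprocessPipeline",
    "clean_outliers",
    "tiered_impute",
    "EmptySubjectError",
    "UnknownCategoryError",
    "PipelineFailureError",
]

LOW_MISSING = 0.05
HIGH_MISSING = 0.20
WINSOR_Z = 3.0
WINSOR_PCTS = (2.5, 97.5)


class EmptySubjectError(ValueError):
    pass


class UnknownCategoryError(ValueError):
    pass


class PipelineFailureError(RuntimeError):
    pass


@dataclass
class FeatureMatrix:
    """Per-patient hourly feature matrices in one tidy frame.

    ``frame`` is indexed by (subject_id, hour) and holds one column per
    feature; ``features`` declares each column's kind and physiologic range.
    """

    frame: pd.DataFrame
    features: List[FeatureDef]

    @property
    def missing_rates(self) -> pd.Series:
        return self.frame.isna().mean()

    def to_array(self, subjects: Optional[Sequence] = None, n_hours: Optional[int] = None):
        """Dense (n_subjects, T, d) array plus the column names."""
        frame = self.frame
        if subjects is not None:
            frame = frame.loc[list(subjects)]
        subs = frame.index.get_level_values(0).unique()
        T = frame.index.get_level_values(1).nunique()
        arr = frame.to_numpy(dtype=float).reshape(len(subs), T, frame.shape[1])
        if n_hours is not None:
            arr = arr[:, :n_hours, :]
        return arr, list(frame.columns), np.asarray(subs)


def resample_hourly(
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    features: Sequence[FeatureDef] = DEFAULT_SCHEMA,
    duration: float = 72.0,
) -> FeatureMatrix:
    """Aggregate long-format events onto a 0-based half-open hourly grid.

    Continuous items keep the last observation inside each bin [h, h+1);
    medication items become presence flags (1 when any administration row
    falls in the bin, else 0); unobserved bins are missing. Static
    demographic columns are broadcast over the stay. A subject with no
    events at all is an error.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n_hours = int(np.ceil(duration))
    features = list(features)
    subjects = demographics["subject_id"].to_numpy()

    ev = events.merge(
        demographics[["subject_id", "admittime"]], on="subject_id", how="left"
    )
    hour = (
        (pd.to_datetime(ev["charttime"]) - pd.to_datetime(ev["admittime"]))
        .dt.total_seconds()
        .floordiv(3600)
        .astype(int)
    )
    ev = ev.assign(hour=hour)
    ev = ev[(ev["hour"] >= 0) & (ev["hour"] < n_hours)]

    observed = set(ev["subject_id"].unique())
    silent = [s for s in subjects if s not in observed]
    if silent:
        raise EmptySubjectError(f"subjects with no events: {silent[:5]}")

    ev = ev.sort_values("charttime", kind="stable")
    last = (
        ev.groupby(["subject_id", "hour", "item"], sort=False)["value"]
        .last()
        .reset_index()
    )
    wide = last.pivot(index=["subject_id", "hour"], columns="item", values="value")
    full_index = pd.MultiIndex.from_product(
        [subjects, range(n_hours)], names=["subject_id", "hour"]
    )
    wide = wide.reindex(full_index)

    cols = {}
    demo = demographics.set_index("subject_id")
    for f in features:
        if f.static:
            cols[f.name] = demo[f.name].reindex(
                wide.index.get_level_values(0)
            ).to_numpy()
        elif f.kind == "binary":
            present = wide[f.name].notna() if f.name in wide else pd.Series(False, index=wide.index)
            cols[f.name] = present.to_numpy(dtype=float)
        else:
            cols[f.name] = (
                pd.to_numeric(wide[f.name], errors="coerce").to_numpy()
                if f.name in wide
                else np.full(len(wide), np.nan)
            )
    frame = pd.DataFrame(cols, index=full_index)
    return FeatureMatrix(frame, features)


def one_hot(
    frame: pd.DataFrame,
    features: Sequence[FeatureDef],
    drop_first: bool = False,
    unseen: str = "error",
) -> tuple[pd.DataFrame, List[FeatureDef]]:
    """Expand categorical columns into indicator columns ``name=category``.

    A missing source value yields missing indicators (routed to imputation
    downstream). An unseen category raises :class:`UnknownCategoryError`
    unless ``unseen='other'``, which routes it to an explicit other column.
    """
    if unseen not in ("error", "other"):
        raise ValueError("unseen must be 'error' or 'other'")
    by_name = {f.name: f for f in features}
    out = {}
    out_defs: List[FeatureDef] = []
    # iterate in input-column order (not roster order) so that re-applying
    # the encoding to an already-expanded frame is an order-preserving no-op
    for name in frame.columns:
        f = by_name.get(name)
        if f is None or f.kind != "categorical":
            out[name] = frame[name].to_numpy()
            out_defs.append(
                f if f is not None
                else FeatureDef(name, "binary" if "=" in name else "continuous")
            )
            continue
        col = frame[name]
        known = set(f.categories)
        strange = set(col.dropna().unique()) - known
        if strange and unseen == "error":
            raise UnknownCategoryError(
                f"{name}: unseen categories {sorted(map(str, strange))}"
            )
        cats = list(f.categories) + (["__other__"] if unseen == "other" else [])
        if drop_first:
            cats = cats[1:]
        isna = col.isna().to_numpy()
        for cat in cats:
            if cat == "__other__":
                ind = (~col.isin(known) & col.notna()).to_numpy(dtype=float)
            else:
                ind = (col == cat).to_numpy(dtype=float)
            cname = f"{name}={cat}"
            out[cname] = np.where(isna, np.nan, ind)
            out_defs.append(FeatureDef(cname, "binary", static=f.static))
    return pd.DataFrame(out, index=frame.index), out_defs


# -- pipeline --------------------------------------------------------------

@dataclass
class _FeatureState:
    kind: str
    source: str  # original roster feature the column derives from
    mean: Optional[float] = None
    sd: Optional[float] = None
    p_low: Optional[float] = None
    p_high: Optional[float] = None
    lower: Optional[float] = None
    upper: Optional[float] = None
    median: Optional[float] = None
    missing_rate: Optional[float] = None
    tier: Optional[str] = None  # 'complete' | 'low' | 'knn' | 'dropped' | 'whitelisted'
    degenerate: bool = False


class PreprocessPipeline:
    """Fit-once, transform-anywhere cleaning pipeline.

    Parameters
    ----------
    features:
        Declared roster (kinds, ranges, categories) of the raw columns.
    whitelist:
        Source-feature names kept (and KNN-imputed) even above 20% missing;
        empty by default — clinical importance is a user judgement.
    k_neighbors:
        Patients considered by the KNN tier (default 5).
    """

    def __init__(
        self,
        features: Sequence[FeatureDef] = DEFAULT_SCHEMA,
        whitelist: Sequence[str] = (),
        k_neighbors: int = 5,
        drop_first: bool = False,
        unseen: str = "error",
    ):
        self.features = list(features)
        self.whitelist = set(whitelist)
        self.k_neighbors = int(k_neighbors)
        self.drop_first = drop_first
        self.unseen = unseen
        self.state: Dict[str, _FeatureState] = {}
        self.modes: Dict[str, float | str] = {}  # categorical source -> mode category
        self.audit_log: List[dict] = []
        self._knn_index: Optional[NearestNeighbors] = None
        self._knn_ref_cols: List[str] = []
        self._knn_train_values: Optional[pd.DataFrame] = None
        self.fitted = False

    # -- helpers ----------------------------------------------------------
    def _log(self, step, feature, count, detail=""):
        self.audit_log.append(
            {"step": step, "feature": feature, "count": int(count), "detail": detail}
        )

    def audit(self) -> pd.DataFrame:
        return pd.DataFrame(self.audit_log)

    def _expand(self, fm: FeatureMatrix) -> tuple[pd.DataFrame, List[FeatureDef]]:
        return one_hot(fm.frame, self.features, self.drop_first, self.unseen)

    def _remove_out_of_range(self, df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        for name, st in self.state.items():
            if st.kind != "continuous" or name not in df.columns:
                continue
            if st.lower is None and st.upper is None:
                continue
            col = df[name]
            bad = pd.Series(False, index=df.index)
            if st.lower is not None:
                bad |= col < st.lower
            if st.upper is not None:
                bad |= col > st.upper
            if bad.any():
                df.loc[bad, name] = np.nan
                self._log("hard_range_removed", name, bad.sum())
        return df

    def _winsorize(self, df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        for name, st in self.state.items():
            if st.kind != "continuous" or name not in df.columns or st.degenerate:
                continue
            col = df[name]
            hi = col > st.mean + WINSOR_Z * st.sd
            lo = col < st.mean - WINSOR_Z * st.sd
            n = int(hi.sum() + lo.sum())
            if n:
                df.loc[hi, name] = st.p_high
                df.loc[lo, name] = st.p_low
                self._log("winsorized", name, n)
        return df

    def _patient_vectors(self, df: pd.DataFrame) -> np.ndarray:
        """Per-patient means of standardized complete continuous features."""
        mat = []
        for name in self._knn_ref_cols:
            st = self.state[name]
            col = df[name].fillna(st.median)
            mat.append(((col - st.mean) / (st.sd if st.sd else 1.0)).to_numpy())
        stacked = np.column_stack(mat)
        frame = pd.DataFrame(stacked, index=df.index)
        return frame.groupby(level=0, sort=False).mean().to_numpy()

    # -- fit --------------------------------------------------------------
    def fit(self, fm: FeatureMatrix) -> "PreprocessPipeline":
        df, defs = self._expand(fm)
        self.state = {
            d.name: _FeatureState(
                kind=d.kind,
                source=d.name.split("=")[0],
                lower=d.lower,
                upper=d.upper,
            )
            for d in defs
        }
        # modes of categorical sources (for all-missing indicator rows)
        for f in self.features:
            if f.kind == "categorical" and f.name in fm.frame.columns:
                vc = fm.frame[f.name].dropna()
                if len(vc):
                    self.modes[f.name] = vc.mode().iloc[0]

        df = self._remove_out_of_range(df)

        # winsorization statistics from the (range-cleaned) training data
        for name, st in self.state.items():
            if st.kind != "continuous":
                continue
            col = df[name].dropna()
            if col.empty or float(col.std(ddof=0)) == 0.0:
                st.degenerate = True
                self._log("winsorize_skipped_degenerate", name, 0)
                continue
            st.mean = float(col.mean())
            st.sd = float(col.std(ddof=0))
            st.p_low, st.p_high = (
                float(np.percentile(col, WINSOR_PCTS[0])),
                float(np.percentile(col, WINSOR_PCTS[1])),
            )
        df = self._winsorize(df)

        # missing rates (computed after removal, which creates missingness)
        rates = df.isna().mean()
        kept_continuous_complete = []
        for name, st in self.state.items():
            st.missing_rate = float(rates[name])
            col = df[name].dropna()
            if st.kind == "continuous":
                st.median = float(col.median()) if len(col) else 0.0
            else:
                st.median = float(col.mode().iloc[0]) if len(col) else 0.0
            if st.missing_rate == 0.0:
                st.tier = "complete"
            elif st.missing_rate < LOW_MISSING:
                st.tier = "low"
            elif st.missing_rate <= HIGH_MISSING:
                st.tier = "knn"
            elif st.source in self.whitelist:
                st.tier = "whitelisted"
                self._log("whitelisted_high_missing", name, 0, f"rate={st.missing_rate:.3f}")
            else:
                st.tier = "dropped"
                self._log("dropped_high_missing", name, 0, f"rate={st.missing_rate:.3f}")
            if st.kind == "continuous" and st.missing_rate < LOW_MISSING and not st.degenerate:
                kept_continuous_complete.append(name)

        if all(st.tier == "dropped" for st in self.state.values()):
            raise PipelineFailureError("every feature was dropped")

        # KNN reference: standardized complete continuous features, per patient
        self._knn_ref_cols = kept_continuous_complete
        knn_cols = [
            n for n, st in self.state.items() if st.tier in ("knn", "whitelisted")
        ]
        if knn_cols and self._knn_ref_cols:
            vectors = self._patient_vectors(df)
            n_train = vectors.shape[0]
            self._knn_index = NearestNeighbors(
                n_neighbors=min(self.k_neighbors, n_train)
            ).fit(vectors)
            self._knn_train_values = df[knn_cols].copy()
        self.fitted = True
        return self

    # -- transform --------------------------------------------------------
    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if not self.fitted:
            raise PipelineFailureError("pipeline must be fitted before transform")
        df, defs = self._expand(fm)
        df = self._remove_out_of_range(df)
        df = self._winsorize(df)

        # mode-impute all-missing categorical indicator groups first, so the
        # one-indicator-per-row contract survives imputation
        for f in self.features:
            if f.kind != "categorical" or f.name not in self.modes:
                continue
            group = [n for n in df.columns if self.state.get(n) and self.state[n].source == f.name]
            if not group:
                continue
            missing_rows = df[group].isna().all(axis=1)
            if missing_rows.any():
                mode_col = f"{f.name}={self.modes[f.name]}"
                for g in group:
                    df.loc[missing_rows, g] = 1.0 if g == mode_col else 0.0
                self._log("mode_imputed_category", f.name, missing_rows.sum())

        drop = [n for n in df.columns if self.state.get(n) and self.state[n].tier == "dropped"]
        if drop:
            df = df.drop(columns=drop)

        # low tier: median (continuous) / mode (indicator) imputation
        for name in df.columns:
            st = self.state.get(name)
            if st is None or st.tier not in ("low", "complete"):
                continue
            n_missing = int(df[name].isna().sum())
            if n_missing:
                df[name] = df[name].fillna(st.median)
                self._log("median_imputed" if st.kind == "continuous" else "mode_imputed",
                          name, n_missing)

        # knn tier (and whitelisted high-missing features)
        knn_cols = [
            n for n in df.columns
            if self.state.get(n) and self.state[n].tier in ("knn", "whitelisted")
        ]
        if knn_cols:
            self._knn_impute(df, knn_cols)

        remaining = df.columns[df.isna().any()].tolist()
        for name in remaining:  # safety net: freeze to train median
            n_missing = int(df[name].isna().sum())
            st = self.state.get(name)
            df[name] = df[name].fillna(st.median if st else 0.0)
            self._log("fallback_median_imputed", name, n_missing)

        out_defs = [
            FeatureDef(d.name, "binary" if "=" in d.name else d.kind,
                       d.lower, d.upper, d.categories, d.static)
            for d in defs
            if d.name in df.columns
        ]
        return FeatureMatrix(df, out_defs)

    def _knn_impute(self, df: pd.DataFrame, cols: List[str]) -> None:
        if self._knn_index is None:
            return
        vectors = self._patient_vectors(df)
        _, neigh = self._knn_index.kneighbors(vectors)
        subjects = df.index.get_level_values(0).unique()
        train_vals = self._knn_train_values
        train_subjects = train_vals.index.get_level_values(0).unique()
        for col in cols:
            tv = train_vals[col].unstack(level=1)  # train patients x hours
            tv_arr = tv.to_numpy()
            obs_counts = np.sum(~np.isnan(tv_arr), axis=1)
            patient_mean = np.where(
                obs_counts > 0,
                np.nansum(tv_arr, axis=1) / np.maximum(obs_counts, 1),
                np.nan,
            )
            series = df[col]
            missing = series.isna()
            if not missing.any():
                continue
            count = 0
            for p_idx, subj in enumerate(subjects):
                rows = missing.loc[subj]
                if not rows.any():
                    continue
                nb = neigh[p_idx]
                nb_vals = tv_arr[nb]  # (K, T)
                counts = np.sum(~np.isnan(nb_vals), axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    hourly = np.where(
                        counts > 0, np.nansum(nb_vals, axis=0) / np.maximum(counts, 1), np.nan
                    )
                finite_pm = patient_mean[nb][np.isfinite(patient_mean[nb])]
                pooled = finite_pm.mean() if finite_pm.size else np.nan
                for h in np.flatnonzero(rows.to_numpy()):
                    v = hourly[h] if h < hourly.size and np.isfinite(hourly[h]) else pooled
                    if not np.isfinite(v):
                        v = self.state[col].median
                    df.loc[(subj, h), col] = v
                    count += 1
            self._log("knn_imputed", col, count, f"k={self.k_neighbors}")
        # avoid neighbour self-matching leak-checks confusion: training
        # patients may be their own nearest neighbour, which is exact recall
        # of their own observed values and is intended.
        _ = train_subjects

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "whitelist": sorted(self.whitelist),
            "k_neighbors": self.k_neighbors,
            "drop_first": self.drop_first,
            "unseen": self.unseen,
            "modes": {k: str(v) for k, v in self.modes.items()},
            "state": {
                name: {k: v for k, v in vars(st).items()}
                for name, st in self.state.items()
            },
            "knn_ref_cols": self._knn_ref_cols,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


# -- single-shot functional forms of the pipeline stages -------------------

def clean_outliers(
    fm: FeatureMatrix, features: Optional[Sequence[FeatureDef]] = None
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Hard-range removal plus 3-SD winsorization, fit on the input itself.

    Returns the cleaned matrix and the audit log. For split-aware use, fit a
    :class:`PreprocessPipeline` on the training split instead.
    """
    pipe = PreprocessPipeline(features or fm.features)
    pipe.fit(fm)
    df, defs = pipe._expand(fm)
    df = pipe._remove_out_of_range(df)
    df = pipe._winsorize(df)
    return FeatureMatrix(df, defs), pipe.audit()


def tiered_impute(
    fm: FeatureMatrix,
    features: Optional[Sequence[FeatureDef]] = None,
    whitelist: Sequence[str] = (),
    k_neighbors: int = 5,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Missing-rate-tiered imputation, fit on the input itself."""
    pipe = PreprocessPipeline(features or fm.features, whitelist, k_neighbors)
    pipe.fit(fm)
    out = pipe.transform(fm)
    return out, pipe.audit()
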