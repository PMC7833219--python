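"""Model/Results interface over the full analysis.

:class:`GeometricStressModel` holds a three-channel recording (HRV, step
frequency, SpO2, plus optional extra channels) and a
:class:`~geostress.config.PipelineConfig`; its :meth:`~GeometricStressModel.fit`
runs resampling → segmentation → Hurst projection → SpO2 perceptron →
domain partition → indices, returning a :class:`StressResults` carrying the
stress indicatrix, the partition, pGSI (τ), pSRI (θ) and per-channel
behavioural entropies, with ``summary()`` and deterministic JSON export.

:class:`PowerLawModel` fits the cross-subject power law α·τ^β ≈ bE and
returns a :class:`PowerLawResults`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as tsio
from .complexity import StressIndicatrix, make_segmentation, stress_indicatrix
from .config import PipelineConfig
from .entropy import behavioural_entropy
from .geometry import (
    DomainPartition,
    GeometryConfig,
    PerceptronTrack,
    StressIndexResult,
    build_perceptron,
    compute_psri,
    partition_domain,
)
from .io import SMSTimeSeries, resample_uniform
from .powerlaw import PowerLawFit, fit_power_law, powerlaw_table

__all__ = [
    "GeometricStressModel",
    "StressResults",
    "PowerLawModel",
    "PowerLawResults",
    "run_pipeline",
]

logger = logging.getLogger("geostress")


class GeometricStressModel:
    """Geometric stress analysis of one multichannel recording.

    Parameters
    ----------
    hrv, sf, spo2 : SMSTimeSeries
        The predictor channels (heart-rate variability, step frequency)
        and the perceptron channel (SpO2).
    extra : mapping, optional
        Further channels (perfusion, skin temperature, movement, …) whose
        behavioural entropy is reported alongside the main three.
    config : PipelineConfig, optional
    """

    def __init__(
        self,
        hrv: SMSTimeSeries,
        sf: SMSTimeSeries,
        spo2: SMSTimeSeries,
        extra: Mapping[str, SMSTimeSeries] | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        self.config = config or PipelineConfig()
        self.channels: dict[str, SMSTimeSeries] = {"HRV": hrv, "SF": sf, "SpO2": spo2}
        if extra:
            for name, series in extra.items():
                if name in self.channels:
                    raise ValueError(f"duplicate channel {name!r}")
                self.channels[name] = series

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        column_map: Mapping[str, str] | None = None,
        *,
        time_column: str = "t",
        config: PipelineConfig | None = None,
    ) -> "GeometricStressModel":
        """Build from a tidy DataFrame with a time column and one column
        per channel (column_map: channel-name → column-name)."""
        if column_map is None:
            lower = {c.lower(): c for c in df.columns}
            column_map = {
                ch: lower[ch.lower()] for ch in tsio.KNOWN_CHANNELS if ch.lower() in lower
            }
        missing = [c for c in column_map.values() if c not in df.columns]
        if missing:
            raise tsio.ConfigurationError(f"mapped column(s) not in frame: {missing}")
        times = tsio._parse_times(df[time_column])
        times = times - times[0]
        channels = {}
        for ch, col in column_map.items():
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            keep = np.isfinite(vals)
            channels[ch] = SMSTimeSeries(ch, times[keep], vals[keep])
        return cls.from_channels(channels, config=config)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        column_map: Mapping[str, str] | None = None,
        *,
        time_column: str = "t",
        config: PipelineConfig | None = None,
    ) -> "GeometricStressModel":
        channels = tsio.read_sms_csv(path, column_map, time_column=time_column)
        return cls.from_channels(channels, config=config)

    @classmethod
    def from_channels(
        cls,
        channels: Mapping[str, SMSTimeSeries],
        config: PipelineConfig | None = None,
    ) -> "GeometricStressModel":
        required = {"HRV", "SF", "SpO2"}
        if not required.issubset(channels):
            raise tsio.ConfigurationError(
                f"need channels {sorted(required)}, got {sorted(channels)}"
            )
        extra = {k: v for k, v in channels.items() if k not in required}
        return cls(
            channels["HRV"], channels["SF"], channels["SpO2"],
            extra=extra or None, config=config,
        )

    def fit(self) -> "StressResults":
        """Run the full analysis and return a results object."""
        cfg = self.config
        logger.info(
            "fit: dt=%s k=%s spp=%s hurst=%s eps=%s mesh=%s classifier=%s "
            "tie-rule=sign(0)->+1",
            cfg.dt, cfg.k, cfg.samples_per_segment, cfg.hurst_method,
            cfg.epsilon, cfg.mesh, cfg.classifier,
        )
        resampled = {
            name: resample_uniform(s, cfg.dt) for name, s in self.channels.items()
        }
        # channels may end on different grid lengths after per-channel
        # missing-value drops; truncate to the common span
        n = min(len(s) for s in resampled.values())
        resampled = {
            name: SMSTimeSeries(s.label, s.times[:n], s.values[:n])
            for name, s in resampled.items()
        }
        hrv, sf, spo2 = resampled["HRV"], resampled["SF"], resampled["SpO2"]

        k = cfg.k if cfg.k is not None else max(2, n // cfg.samples_per_segment)
        seg = make_segmentation(hrv.times[0], hrv.times[-1], k)
        indicatrix = stress_indicatrix(
            hrv, sf, spo2, seg,
            method=cfg.hurst_method, min_samples=cfg.min_segment_samples,
        )
        perceptron = build_perceptron(indicatrix.spo2)

        # pair points with labels on segments where all three tracks are valid
        valid = (
            indicatrix.hrv.valid & indicatrix.sf.valid & indicatrix.spo2.valid
        )
        pts = np.column_stack(
            [indicatrix.hrv.values[valid], indicatrix.sf.values[valid]]
        )
        spo2_valid = indicatrix.spo2.valid
        label_for_segment = np.full(seg.k, 0, dtype=int)
        label_for_segment[spo2_valid] = perceptron.labels
        labels = label_for_segment[valid]

        geo_cfg = GeometryConfig(
            epsilon=cfg.epsilon, mesh=cfg.mesh, classifier=cfg.classifier
        )
        partition = partition_domain(pts, labels, geo_cfg)
        index = compute_psri(pts, labels, partition)

        entropies: dict[str, dict[str, float]] = {}
        tracks = {"HRV": indicatrix.hrv, "SF": indicatrix.sf, "SpO2": indicatrix.spo2}
        from .complexity import complexity_track

        for name, series in resampled.items():
            if name not in tracks:
                tracks[name] = complexity_track(
                    series, seg,
                    method=cfg.hurst_method, min_samples=cfg.min_segment_samples,
                )
        for name, track in tracks.items():
            entropies[name] = {
                "global": behavioural_entropy(track, "global").value,
                "local": behavioural_entropy(track, "local").value,
            }

        return StressResults(
            model=self,
            segmentation=seg,
            indicatrix=indicatrix,
            perceptron=perceptron,
            partition=partition,
            index=index,
            entropies=entropies,
        )


class StressResults:
    """Fitted quantities of one recording: indicatrix, perceptron, domain
    partition, τ (pGSI), θ (pSRI) and per-channel behavioural entropies."""

    def __init__(
        self,
        model: GeometricStressModel,
        segmentation,
        indicatrix: StressIndicatrix,
        perceptron: PerceptronTrack,
        partition: DomainPartition,
        index: StressIndexResult,
        entropies: dict[str, dict[str, float]],
    ) -> None:
        self.model = model
        self.segmentation = segmentation
        self.indicatrix = indicatrix
        self.perceptron = perceptron
        self.partition = partition
        self.index = index
        self.entropies = entropies

    # headline indices ----------------------------------------------------
    @property
    def pgsi(self) -> float:
        """τ — positive (normoxemia) area fraction of the effective domain."""
        return self.index.tau

    tau = pgsi

    @property
    def psri(self) -> float:
        """θ — mean distance of normoxemic points to the hypoxemia boundary."""
        return self.index.theta

    theta = psri

    @property
    def m_plus(self) -> int:
        return self.index.m_plus

    def entropy(self, channel: str, variant: str | None = None) -> float:
        variant = variant or self.model.config.entropy_variant
        return self.entropies[channel][variant]

    # presentation --------------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.config
        k = self.segmentation.k
        lines = [
            "Geometric Stress Analysis Results",
            "=" * 45,
            f"{'segments (k)':<28}{k:>17d}",
            f"{'samples per segment (mean)':<28}{self.indicatrix.hrv.counts.mean():>17.1f}",
            f"{'Hurst estimator':<28}{cfg.hurst_method:>17}",
            f"{'perceptron threshold E[H(Z)]':<28}{self.perceptron.threshold:>17.4f}",
            f"{'positive labels (γ=+1)':<28}{int((self.perceptron.labels == 1).sum()):>17d}",
            f"{'negative labels (γ=−1)':<28}{int((self.perceptron.labels == -1).sum()):>17d}",
            "-" * 45,
            f"{'pGSI (τ)':<28}{self.pgsi:>17.4f}",
            f"{'pSRI (θ)':<28}{self.psri:>17.4f}",
            f"{'m+':<28}{self.m_plus:>17d}",
            "-" * 45,
            "behavioural entropy            global      local",
        ]
        for ch, e in self.entropies.items():
            name = f"bE({ch})"
            lines.append(f"  {name:<22}{e['global']:>11.4f}{e['local']:>11.4f}")
        lines.append("=" * 45)
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "config": asdict(self.model.config),
            "segmentation": {
                "k": int(self.segmentation.k),
                "boundaries": self.segmentation.boundaries.tolist(),
            },
            "indicatrix": {
                "HRV": _track_json(self.indicatrix.hrv),
                "SF": _track_json(self.indicatrix.sf),
                "SpO2": _track_json(self.indicatrix.spo2),
            },
            "perceptron": {
                "labels": self.perceptron.labels.tolist(),
                "threshold": self.perceptron.threshold,
                "excluded_segments": self.perceptron.excluded.tolist(),
            },
            "partition": self.partition.to_json_dict(),
            "indices": {
                "pGSI": self.pgsi,
                "pSRI": None if not np.isfinite(self.psri) else self.psri,
                "m_plus": self.m_plus,
                "theta_flag": self.index.theta_flag,
            },
            "behavioural_entropy": self.entropies,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_json_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def plot_diagram(self, ax=None):
        """Stress-prediction diagram: partitioned domain + labelled points."""
        from .plotting import plot_stress_diagram

        pts_valid = (
            self.indicatrix.hrv.valid
            & self.indicatrix.sf.valid
            & self.indicatrix.spo2.valid
        )
        pts = np.column_stack(
            [self.indicatrix.hrv.values[pts_valid], self.indicatrix.sf.values[pts_valid]]
        )
        lab = np.full(self.segmentation.k, 0, dtype=int)
        lab[self.indicatrix.spo2.valid] = self.perceptron.labels
        return plot_stress_diagram(self.partition, pts, lab[pts_valid], ax=ax)


def _track_json(track) -> dict:
    return {
        "H": [None if not np.isfinite(v) else float(v) for v in track.values],
        "counts": track.counts.tolist(),
    }


class PowerLawModel:
    """Power law α·τ^β ≈ bE across subjects or replicates.

    Parameters
    ----------
    tau : array
        Stress-index values (one per subject/replicate), in (0, 1].
    be : array or mapping channel → array
        Matching behavioural-entropy values; a mapping fits one law per
        channel against the shared τ (the pooled, one-law-per-channel mode).
    """

    def __init__(self, tau, be) -> None:
        self.tau = np.asarray(tau, dtype=float)
        self.be = be

    def fit(self) -> "PowerLawResults":
        if isinstance(self.be, Mapping):
            fits = {ch: fit_power_law(self.tau, v) for ch, v in self.be.items()}
            table = powerlaw_table(dict(self.be), self.tau)
            return PowerLawResults(fits=fits, table=table)
        fit = fit_power_law(self.tau, np.asarray(self.be, dtype=float))
        return PowerLawResults(fits={"bE": fit}, table=None)


class PowerLawResults:
    """One or more fitted power laws with a Table-2-style summary."""

    def __init__(self, fits: dict[str, PowerLawFit], table: pd.DataFrame | None) -> None:
        self.fits = fits
        self.table = table

    @property
    def fit(self) -> PowerLawFit:
        """The single fit, when exactly one channel was given."""
        if len(self.fits) != 1:
            raise ValueError("multiple channels fitted; use .fits[channel]")
        return next(iter(self.fits.values()))

    @property
    def amplitude(self) -> float:
        return self.fit.amplitude

    @property
    def exponent(self) -> float:
        return self.fit.exponent

    @property
    def residual(self) -> float:
        return self.fit.residual

    def predict(self, tau):
        return self.fit.predict(tau)

    def summary(self) -> str:
        lines = [
            "Power-law fits  bE ≈ α·τ^β",
            "=" * 58,
            f"{'channel':<18}{'α':>10}{'β':>10}{'scaled l2':>10}{'n':>6}",
            "-" * 58,
        ]
        for ch, f in self.fits.items():
            lines.append(
                f"{ch:<18}{f.amplitude:>10.4g}{f.exponent:>10.4g}"
                f"{f.residual:>10.3g}{f.tau.size:>6d}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {ch: f.to_json_dict() for ch, f in self.fits.items()}


def run_pipeline(config: PipelineConfig, input_path: str | Path) -> dict:
    """End-to-end CSV → result bundle (the CLI's compute path).

    Deterministic for a fixed config and input; the returned dict is the
    JSON-serializable bundle with every intermediate artifact.
    """
    model = GeometricStressModel.from_csv(
        input_path, config.column_map, time_column=config.time_column, config=config
    )
    results = model.fit()
    return results.to_json_dict()
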