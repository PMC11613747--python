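"""Model/Results surface for birth-prevalence estimation.

:class:`BirthPrevalenceModel` is built from a curated variant table (a
list of :class:`~argprev.records.VariantRecord`, a pandas DataFrame in the
canonical column layout, or the packaged fixture tables) together with an
inclusion model identifier A-G.  ``fit()`` runs selection, exact
allele-frequency aggregation and the Hardy-Weinberg conversion, returning
a :class:`BirthPrevalenceResults` that carries the estimates and a
``summary()`` table.

Example
-------
>>> from argprev import BirthPrevalenceModel
>>> from argprev.simulate import make_fixtures
>>> published, unpublished = make_fixtures()
>>> res = BirthPrevalenceModel(published + unpublished, model="D").fit()
>>> res.n_selected
19
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import pandas as pd

from .acmg import CombinerConfig, classify
from .prevalence import (
    DEFAULT_CONVENTION,
    MODELS,
    AlleleFrequencyConvention,
    HardyWeinbergResult,
    ModelRun,
    SelectionReport,
    run_model,
)
from .records import VariantRecord, _record_from_row

__all__ = ["BirthPrevalenceModel", "BirthPrevalenceResults"]


class BirthPrevalenceModel:
    """Recessive-disease birth-prevalence estimator for one inclusion model.

    Parameters
    ----------
    records : sequence of VariantRecord
        The curated variant table (published and/or database variants).
    model : str
        Inclusion model identifier, one of ``"A"`` through ``"G"``.
    convention : AlleleFrequencyConvention
        Missing-allele-frequency conventions.
    use_engine_labels : bool or CombinerConfig
        When truthy, classification labels are recomputed from each
        record's evidence with the rules engine (points system by default,
        or the given :class:`CombinerConfig`) instead of using the
        curator-assigned labels.
    """

    def __init__(
        self,
        records: Sequence[VariantRecord],
        model: str = "E",
        convention: AlleleFrequencyConvention = DEFAULT_CONVENTION,
        use_engine_labels=False,
    ) -> None:
        model = model.upper()
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; expected one of A..G")
        self.records = list(records)
        self.model_id = model
        self.convention = convention
        self._engine_config: Optional[CombinerConfig]
        if use_engine_labels:
            self._engine_config = (
                use_engine_labels
                if isinstance(use_engine_labels, CombinerConfig)
                else CombinerConfig()
            )
        else:
            self._engine_config = None

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "BirthPrevalenceModel":
        """Build from a DataFrame in the canonical variant-table layout."""
        records = [
            _record_from_row({k: v for k, v in row.items() if pd.notna(v)}, line_no=i + 2)
            for i, row in enumerate(frame.to_dict(orient="records"))
        ]
        return cls(records, **kwargs)

    @property
    def spec(self):
        return MODELS[self.model_id]

    def fit(self) -> "BirthPrevalenceResults":
        engine_labels = None
        if self._engine_config is not None:
            engine_labels = {
                rec.dedup_key: classify(rec.evidence, self._engine_config).label
                for rec in self.records
            }
        run = run_model(
            self.records, self.model_id, convention=self.convention,
            engine_labels=engine_labels,
        )
        return BirthPrevalenceResults(model=self, run=run)


@dataclass(frozen=True)
class BirthPrevalenceResults:
    """Fitted estimates: q, carrier frequency, birth prevalence."""

    model: BirthPrevalenceModel
    run: ModelRun

    @property
    def q(self) -> Fraction:
        """Summed qualifying allele frequency (exact)."""
        return self.run.q

    @property
    def q_per_100k(self) -> float:
        return float(self.run.q * self.model.convention.normalization_base)

    @property
    def hw(self) -> HardyWeinbergResult:
        return self.run.hw

    @property
    def prevalence_one_in(self) -> int:
        return self.run.hw.prevalence_one_in

    @property
    def carrier_one_in(self) -> int:
        return self.run.hw.carrier_one_in

    @property
    def carrier_rate_simple(self) -> float:
        return float(self.run.hw.carrier_rate_simple)

    @property
    def n_selected(self) -> int:
        return self.run.report.n_selected

    @property
    def selection(self) -> SelectionReport:
        return self.run.report

    def to_dict(self) -> dict:
        rep = self.run.report
        return {
            "model": self.model.model_id,
            "q_per_100k": self.q_per_100k,
            "carrier_one_in": self.carrier_one_in,
            "prevalence_one_in": self.prevalence_one_in,
            "carrier_rate_simple": self.carrier_rate_simple,
            "n_selected": rep.n_selected,
            "n_published_selected": rep.n_published_selected,
            "n_unpublished_selected": rep.n_unpublished_selected,
        }

    def summary(self) -> str:
        spec = self.model.spec
        rep = self.run.report
        rows = [
            ("Inclusion model", f"{spec.model_id} ({spec.description})"),
            ("Input variants", f"{rep.n_input}"),
            ("Selected variants",
             f"{rep.n_selected} ({rep.n_published_selected} published, "
             f"{rep.n_unpublished_selected} unpublished)"),
            ("q (per 100,000 alleles)", f"{self.q_per_100k:g}"),
            ("Carrier rate (2q, alleles/individual)", f"{self.carrier_rate_simple:.6f}"),
            ("Carrier frequency (2pq)", f"1 in {self.carrier_one_in:,}"),
            ("Birth prevalence (q^2)", f"1 in {self.prevalence_one_in:,}"),
        ]
        width = max(len(name) for name, _ in rows)
        lines = ["Birth prevalence estimate (Hardy-Weinberg)",
                 "=" * 46]
        lines += [f"{name.ljust(width)}  {value}" for name, value in rows]
        return "\n".join(lines)
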