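"""Scikit-learn-style front end for the decision tree.

The procedure has no training step — its parameters are fixed by legislation
and configuration — so ``fit`` validates the configuration and freezes the
fitted attributes, and ``predict`` labels each food for each configured
nutrient.  The estimator composes with sklearn pipelines and clones cleanly
via ``get_params``/``set_params``.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .classifier import classify_dataset, classify_food
from .config import load_config
from .io import DatasetDialect, records_from_frame
from .model import LABELS, BrandedFoodRecord


class FortificationClassifier(BaseEstimator):
    """Label foods fortified / non-fortified / ineligible per micronutrient.

    Parameters
    ----------
    config:
        ``None`` for the packaged defaults, a YAML path, or a mapping merged
        over the defaults.
    nutrients:
        Restrict classification to these nutrient ids (default: all
        configured).
    dialect:
        Column mapping applied when ``X`` is a DataFrame.

    Examples
    --------
    >>> clf = FortificationClassifier(nutrients=["calcium"]).fit([])
    >>> record = BrandedFoodRecord(
    ...     food_id="f1", food_group="Bread",
    ...     ingredient_list="tarwebloem, calciumcarbonaat, zout",
    ...     nutrient_values={"calcium": 150.0})
    >>> clf.predict([record])
    array([['fortified']], dtype=object)
    """

    def __init__(
        self,
        config=None,
        nutrients: Optional[Sequence[str]] = None,
        dialect: Optional[DatasetDialect] = None,
    ):
        self.config = config
        self.nutrients = nutrients
        self.dialect = dialect

    def fit(self, X=None, y=None) -> "FortificationClassifier":
        """Validate the configuration; no parameters are learned."""
        self.config_ = load_config(self.config, nutrients=self.nutrients)
        self.nutrients_ = np.asarray(self.config_.nutrient_ids, dtype=object)
        self.classes_ = np.asarray(LABELS, dtype=object)
        return self

    def _records(
        self, X: Union[pd.DataFrame, Sequence[BrandedFoodRecord]]
    ) -> list[BrandedFoodRecord]:
        if isinstance(X, pd.DataFrame):
            return records_from_frame(X, self.dialect)
        return list(X)

    def predict(self, X) -> np.ndarray:
        """Labels with shape (n_samples, n_nutrients), columns in
        ``nutrients_`` order."""
        check_is_fitted(self, "config_")
        records = self._records(X)
        out = np.empty((len(records), len(self.nutrients_)), dtype=object)
        for i, record in enumerate(records):
            for j, result in enumerate(classify_food(record, self.config_)):
                out[i, j] = result.label
        return out

    def transform(self, X) -> pd.DataFrame:
        """Full results table (one row per food x nutrient with step
        outcomes); the audit-friendly sibling of :meth:`predict`."""
        check_is_fitted(self, "config_")
        frame, _ = classify_dataset(self._records(X), self.config_)
        return frame

    def classify(self, X, include_trace: bool = False):
        """Results table plus the per-step tally."""
        check_is_fitted(self, "config_")
        return classify_dataset(self._records(X), self.config_, include_trace)
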