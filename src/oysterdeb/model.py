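"""Model/Results interface over the estimation machinery.

:class:`DEBModel` binds a species parameter set to a collection of
observation datasets; ``fit()`` runs the covariation Nelder-Mead
minimisation of the MRE loss and returns a :class:`DEBResults` carrying
the estimates, fit diagnostics and a ``summary()`` table. Simulation
and plotting hang off the results object.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .estimation import (
    Dataset,
    EstimationResult,
    estimate,
    loss_mre,
    predict_all,
    predict_dataset,
)
from .params import DEBParams

__all__ = ["DEBModel", "DEBResults"]


class DEBModel:
    """A DEB model bound to observation data for estimation.

    Parameters
    ----------
    datasets : sequence of ZeroVariateDatum / UniVariateDataset
        The observations (the estimation target).
    params : DEBParams
        Starting parameter set (the 'pars_init' role).
    free : sequence of str
        Primary parameters to estimate; the rest stay fixed.
    bounds : mapping, optional
        {name: (lo, hi)} box constraints on the natural scale.
    symmetric : bool
        Use the symmetric-relative-error loss variant instead of the
        root-weighted-mean squared relative error.
    """

    def __init__(
        self,
        datasets: Sequence[Dataset],
        params: DEBParams,
        free: Sequence[str] = (),
        bounds: Optional[Mapping[str, tuple]] = None,
        symmetric: bool = False,
    ):
        self.datasets = list(datasets)
        if not self.datasets:
            raise ValueError("DEBModel needs at least one dataset")
        self.start_params = params
        self.free = tuple(free)
        self.bounds = dict(bounds) if bounds else None
        self.symmetric = symmetric

    @classmethod
    def from_species(cls, species: str, datasets: Sequence[Dataset], **kwargs) -> "DEBModel":
        """Build from one of the packaged species parameter files."""
        from .io import load_species

        return cls(datasets, load_species(species), **kwargs)

    def predict(self, params: Optional[DEBParams] = None) -> dict:
        """Predictions for every dataset at ``params`` (default: start)."""
        return predict_all(params or self.start_params, self.datasets)

    def loss(self, params: Optional[DEBParams] = None) -> float:
        """MRE loss at ``params`` (default: the starting parameters)."""
        p = params or self.start_params
        return loss_mre(self.datasets, predict_all(p, self.datasets),
                        symmetric=self.symmetric)

    def fit(
        self,
        max_iterations: int = 2000,
        restarts: int = 3,
        seed: Optional[int] = None,
        fatol: float = 1e-6,
    ) -> "DEBResults":
        """Covariation Nelder-Mead fit; returns a results object."""
        res = estimate(
            self.start_params, self.datasets, free=self.free, bounds=self.bounds,
            max_iterations=max_iterations, restarts=restarts, seed=seed,
            symmetric=self.symmetric, fatol=fatol,
        )
        return DEBResults(self, res)


class DEBResults:
    """Fit results: estimates, per-dataset errors, diagnostics."""

    def __init__(self, model: DEBModel, result: EstimationResult):
        self.model = model
        self._result = result
        self.params: DEBParams = result.params
        self.mre: float = result.mre
        self.re_per_dataset: dict = result.re_per_dataset
        self.trace = result.trace
        self.converged: bool = result.converged

    # -- tables ---------------------------------------------------------

    def parameter_table(self):
        return self._result.parameter_table()

    def summary(self) -> str:
        """Plain-text fit report (parameters, loss, per-dataset errors)."""
        lines = []
        w = 64
        lines.append("DEB covariation fit".center(w))
        lines.append("=" * w)
        lines.append(f"{'species:':<22}{self.model.start_params.name or '<unnamed>'}")
        lines.append(f"{'datasets:':<22}{len(self.model.datasets)}")
        lines.append(f"{'free parameters:':<22}{', '.join(self._result.free) or '(none)'}")
        lines.append(f"{'loss (MRE):':<22}{self.mre:.6g}")
        lines.append(f"{'converged:':<22}{self.converged}")
        lines.append(f"{'loss evaluations:':<22}{self._result.n_evaluations}")
        if self._result.free:
            lines.append("-" * w)
            lines.append(f"{'parameter':<12}{'start':>14}{'estimate':>14}{'change %':>12}")
            for name in self._result.free:
                a = getattr(self._result.start_params, name)
                b = getattr(self.params, name)
                lines.append(f"{name:<12}{a:>14.6g}{b:>14.6g}{100*(b-a)/a:>12.2f}")
        lines.append("-" * w)
        lines.append(f"{'dataset':<28}{'RE':>12}")
        for name, re in self.re_per_dataset.items():
            lines.append(f"{name:<28}{re:>12.4g}")
        lines.append("=" * w)
        return "\n".join(lines)

    # -- downstream use ---------------------------------------------------

    def predict(self, dataset: Optional[Dataset] = None):
        """Predictions at the fitted parameters (one dataset or all)."""
        if dataset is not None:
            return predict_dataset(self.params, dataset)
        return predict_all(self.params, self.model.datasets)

    def simulate(self, forcing, init, horizon, **kwargs):
        """Forward simulation at the fitted parameters."""
        from .simulate import simulate as _simulate

        return _simulate(self.params, forcing, init, horizon, **kwargs)

    def plot_fit(self, ax=None):
        """Observations vs fitted predictions for the uni-variate datasets."""
        import matplotlib.pyplot as plt

        from .estimation import UniVariateDataset

        if ax is None:
            _, ax = plt.subplots()
        preds = self.predict()
        for ds in self.model.datasets:
            if not isinstance(ds, UniVariateDataset):
                continue
            pts = ax.plot(ds.x, ds.y, "o", label=f"{ds.name} (obs)")
            ax.plot(ds.x, preds[ds.name], "-", color=pts[0].get_color())
        ax.set_xlabel("abscissa")
        ax.set_ylabel("observable")
        ax.legend(fontsize="x-small")
        return ax

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<DEBResults MRE={self.mre:.4g} free={self._result.free} "
                f"converged={self.converged}>")
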