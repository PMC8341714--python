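"""Model / Results interface for the Dirichlet-process PRS sampler.

:class:`DirichletProcessPRS` is constructed from aligned summary
statistics and a block LD reference; :meth:`DirichletProcessPRS.fit` runs
the blocked Gibbs sampler and returns a
:class:`DirichletProcessPRSResults` carrying posterior-mean effects,
per-SNP inclusion frequencies and diagnostic traces (per-iteration
heritability beta' R beta and occupied-cluster count). ``run_mcmc`` is the
equivalent functional entry point.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DivergenceError, InputError
from .gibbs import DPPrior, DPState, MCMCConfig, gibbs_sweep, init_state
from .likelihood import BlockQuadratics, LikelihoodSpec, build_block_quadratics
from .sumstats import SummaryStats, write_effects

DIVERGENCE_BOUND = 1e3


class DirichletProcessPRS:
    """Nonparametric-prior polygenic score model from summary statistics.

    Parameters
    ----------
    sumstats : SummaryStats
        QCed and allele-aligned to ``ldref`` (same SNPs, same order, same
        effect alleles).
    ldref : LDReference
        Shrunken block-diagonal reference LD.
    likelihood : LikelihoodSpec, optional
        Defaults to the regularized likelihood with aN = 0.1, c = 1.
    prior : DPPrior, optional
        Defaults to K = 1000 components, Uniform(0, 1) base on the
        standard-deviation scale, Gamma(0.1, 0.1) concentration
        hyperprior, N(0, 1) prior on the expansion parameter.
    """

    def __init__(self, sumstats, ldref, likelihood=None, prior=None):
        self.sumstats = sumstats
        self.ldref = ldref
        self.likelihood = likelihood or LikelihoodSpec()
        self.prior = prior or DPPrior()
        self.quadratics: BlockQuadratics = build_block_quadratics(
            ldref, sumstats, self.likelihood
        )

    @classmethod
    def from_files(cls, ss_path, ldref_dir, likelihood=None, prior=None, qc=True):
        """Read summary statistics and a saved LD reference, QC and align."""
        from .ld import LDReference
        from .sumstats import QCConfig, align_alleles, qc_filter, read_summary_stats

        ss = read_summary_stats(ss_path)
        if qc:
            ss, _ = qc_filter(ss, QCConfig())
        ldref = LDReference.load(ldref_dir)

        class _MetaPanel:  # align against the reference's metadata
            meta = ldref.meta

        ss, _ = align_alleles(ss, _MetaPanel())
        keep = pd.Index(ldref.meta["snp_id"]).isin(ss.df["snp_id"])
        if not keep.all():
            ldref = ldref.restrict(np.asarray(keep))
        return cls(ss, ldref, likelihood=likelihood, prior=prior)

    def fit(
        self,
        n_iter: int = 1000,
        burn_in: int = 200,
        thin: int = 1,
        seed: int = 0,
        n_threads: int = 1,
        use_numba: bool = True,
        callback=None,
    ) -> "DirichletProcessPRSResults":
        """Run the blocked Gibbs sampler.

        ``callback(iteration, state)``, if given, is invoked after every
        sweep (diagnostics / invariant checking). Raises
        :class:`DivergenceError` if any |beta| exceeds 1e3, which indicates
        a likelihood/reference mismatch; the regularized likelihood is the
        recommended remedy.
        """
        cfg = MCMCConfig(
            n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed, n_threads=n_threads
        )
        return self._run(cfg, use_numba=use_numba, callback=callback)

    def _run(self, cfg: MCMCConfig, use_numba=True, callback=None):
        quads = self.quadratics
        n_blocks = len(quads.bounds)
        m = quads.n_snps
        master = np.random.SeedSequence(cfg.seed)
        children = master.spawn(n_blocks + 1)
        global_rng = np.random.Generator(np.random.PCG64(children[0]))
        block_rngs = [np.random.Generator(np.random.PCG64(c)) for c in children[1:]]

        state = init_state(m, self.prior, global_rng)
        n_kept = 0
        beta_sum = np.zeros(m)
        nonzero_sum = np.zeros(m)
        h2_trace = np.empty(cfg.n_iter)
        cluster_trace = np.empty(cfg.n_iter, dtype=int)
        eta_trace = np.empty(cfg.n_iter)
        alpha_trace = np.empty(cfg.n_iter)

        for it in range(cfg.n_iter):
            gibbs_sweep(
                quads,
                state,
                self.prior,
                block_rngs,
                global_rng,
                n_threads=cfg.n_threads,
                use_numba=use_numba,
            )
            beta = state.beta
            if np.max(np.abs(beta)) > DIVERGENCE_BOUND:
                raise DivergenceError(
                    f"MCMC diverged at iteration {it} (max |beta| > {DIVERGENCE_BOUND:g}). "
                    "This usually indicates a mismatch between the summary statistics "
                    "and the reference panel; rerun with the regularized likelihood "
                    "(mode='regularized', aN > 0)."
                )
            h2 = 0.0
            for (s, e), R in zip(quads.bounds, quads.R):
                b = beta[s:e]
                if np.any(b):
                    h2 += float(b @ (R @ b))
            h2_trace[it] = h2
            occupied = np.unique(state.z)
            cluster_trace[it] = int(np.sum(occupied > 0))
            eta_trace[it] = state.eta
            alpha_trace[it] = state.alpha
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                n_kept += 1
                beta_sum += beta
                nonzero_sum += state.z > 0
            if callback is not None:
                callback(it, state)

        return DirichletProcessPRSResults(
            model=self,
            config=cfg,
            posterior_mean=beta_sum / n_kept,
            nonzero_freq=nonzero_sum / n_kept,
            h2_trace=h2_trace,
            cluster_trace=cluster_trace,
            eta_trace=eta_trace,
            alpha_trace=alpha_trace,
            n_kept=n_kept,
            final_state=state,
        )


@dataclass
class DirichletProcessPRSResults:
    """Posterior summary of a fitted model.

    ``posterior_mean`` is the per-SNP posterior-mean effect on the
    (rescaled) standardized scale — the PRS weights. ``nonzero_freq`` is
    the fraction of retained iterations in which a SNP escaped the point
    mass (a variable-selection diagnostic, not a calibrated PIP). The
    heritability trace beta' R beta is a convergence diagnostic.
    """

    model: DirichletProcessPRS
    config: MCMCConfig
    posterior_mean: np.ndarray
    nonzero_freq: np.ndarray
    h2_trace: np.ndarray
    cluster_trace: np.ndarray
    eta_trace: np.ndarray
    alpha_trace: np.ndarray
    n_kept: int
    final_state: DPState

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            self.posterior_mean, index=self.model.ldref.meta["snp_id"], name="effect"
        )

    def effects_frame(self) -> pd.DataFrame:
        meta = self.model.ldref.meta
        return pd.DataFrame(
            {"SNP": meta["snp_id"], "A1": meta["a1"], "EFFECT": self.posterior_mean}
        )

    def save_effects(self, path) -> None:
        df = self.effects_frame()
        write_effects(path, df["SNP"], df["A1"], df["EFFECT"])

    def predict(self, panel) -> np.ndarray:
        """Polygenic scores for a genotype panel aligned to the model SNPs."""
        from .plinkio import score_prs

        if hasattr(panel, "meta"):
            if not np.array_equal(
                panel.meta["snp_id"].to_numpy(),
                self.model.ldref.meta["snp_id"].to_numpy(),
            ):
                raise InputError("panel SNPs do not match the fitted model")
            return score_prs(panel, self.posterior_mean)
        return score_prs(panel, self.posterior_mean)

    def summary(self) -> str:
        keep = slice(self.config.burn_in, None)
        h2 = self.h2_trace[keep]
        buf = io.StringIO()
        w = buf.write
        w("Dirichlet-process PRS results\n")
        w("=" * 60 + "\n")
        w(f"{'SNPs':<34}{self.posterior_mean.shape[0]:>26}\n")
        w(f"{'LD blocks':<34}{len(self.model.quadratics.bounds):>26}\n")
        w(f"{'Likelihood':<34}{self.model.likelihood.mode:>26}\n")
        if self.model.likelihood.mode == "regularized":
            w(f"{'aN':<34}{self.model.likelihood.aN:>26g}\n")
        w(f"{'Input scale c':<34}{self.model.likelihood.c:>26g}\n")
        w(f"{'Components (K)':<34}{self.model.prior.K:>26}\n")
        w(f"{'Iterations (kept)':<34}{f'{self.config.n_iter} ({self.n_kept})':>26}\n")
        w(f"{'Seed':<34}{self.config.seed:>26}\n")
        w("-" * 60 + "\n")
        w(f"{'Posterior mean h2 (diagnostic)':<34}{np.mean(h2):>26.4f}\n")
        w(f"{'Occupied clusters (final)':<34}{self.cluster_trace[-1]:>26}\n")
        w(f"{'SNPs with P(nonzero) > 0.5':<34}{int(np.sum(self.nonzero_freq > 0.5)):>26}\n")
        w(f"{'Max |posterior mean effect|':<34}{np.max(np.abs(self.posterior_mean)):>26.3e}\n")
        w("=" * 60 + "\n")
        return buf.getvalue()

    def plot_traces(self, path=None):
        """Diagnostic trace plots (heritability, clusters, eta, alpha)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 2, figsize=(9, 6))
        for ax, (trace, name) in zip(
            axes.ravel(),
            [
                (self.h2_trace, "h2 = beta' R beta"),
                (self.cluster_trace, "occupied clusters"),
                (self.eta_trace, "eta"),
                (self.alpha_trace, "alpha"),
            ],
        ):
            ax.plot(trace, lw=0.7)
            ax.axvline(self.config.burn_in, color="r", ls="--", lw=0.7)
            ax.set_title(name)
            ax.set_xlabel("iteration")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def run_mcmc(
    ldref, ss, spec=None, prior=None, cfg: MCMCConfig | None = None, callback=None,
    use_numba: bool = True,
) -> DirichletProcessPRSResults:
    """Functional wrapper: build the model and fit it in one call."""
    cfg = cfg or MCMCConfig()
    model = DirichletProcessPRS(ss, ldref, likelihood=spec, prior=prior)
    return model._run(cfg, callback=callback, use_numba=use_numba)


#: alias matching the domain vocabulary: the fitted object is the
#: posterior summary of the per-SNP effects
PosteriorSummary = DirichletProcessPRSResults
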