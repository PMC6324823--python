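"""Generative model of one afferent connection.

In cortex a single glutamatergic axon forms on the order of five synapses
with a target pyramidal neuron; a fraction of them are AMPA-silent
(NMDA-receptor responses only). Each synapse releases a vesicle
independently per stimulus with probability p; quantal amplitudes are
gamma-distributed (positive support) with a mean and coefficient of
variation per receptor class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SynapseModel:
    """Parameters of one simulated afferent connection.

    The realized number of silent synapses is ``round(n_synapses *
    silent_fraction)``; recovery studies should compare estimates
    against :attr:`realized_silent_fraction`, the fraction actually
    representable at integer synapse counts. All synapses carry NMDA
    receptors with identical quantal amplitude — the assumption under
    which the log-ratio estimator is exact.
    """

    n_synapses: int = 5
    silent_fraction: float = 0.4
    release_prob: float = 0.3
    quantal_mean_ampa_pA: float = 10.0
    quantal_cv: float = 0.3
    quantal_mean_nmda_pA: float = 10.0
    noise_sd_pA: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_synapses < 1:
            raise ValueError("n_synapses must be a positive integer")
        if not 0.0 <= self.silent_fraction <= 1.0:
            raise ValueError("silent_fraction must lie in [0, 1]")
        if not 0.0 <= self.release_prob <= 1.0:
            raise ValueError("release_prob must lie in [0, 1]")
        if self.quantal_cv < 0 or self.noise_sd_pA < 0:
            raise ValueError("quantal_cv and noise_sd_pA must be non-negative")
        if self.quantal_mean_ampa_pA < 0 or self.quantal_mean_nmda_pA < 0:
            raise ValueError("quantal means must be non-negative")

    @property
    def n_silent(self) -> int:
        return int(round(self.n_synapses * self.silent_fraction))

    @property
    def n_active(self) -> int:
        """Synapses with functional AMPA-receptor transmission."""
        return self.n_synapses - self.n_silent

    @property
    def realized_silent_fraction(self) -> float:
        return self.n_silent / self.n_synapses

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)
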