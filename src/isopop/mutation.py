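"""Microsatellite mutation models shared by the forward and coalescent engines."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MutationModel:
    """A mutation process for microsatellite loci.

    kind
        ``KAM`` (K-allele: a mutation picks uniformly among ``n_states``),
        ``SMM`` (strict stepwise: +-1 repeat unit), or ``TPM`` (two-phase:
        single step with probability 1 - p_multistep, otherwise a multi-step
        of at least two repeat units with size 1 + Geometric and mean
        ``delta_g``, sign equiprobable).
    rate
        Mutation probability per allele copy per generation.
    """

    kind: str = "SMM"
    rate: float = 2e-4
    n_states: int = 15
    p_multistep: float = 0.0
    delta_g: float = 3.1

    def __post_init__(self) -> None:
        if self.kind not in {"KAM", "SMM", "TPM"}:
            raise ValueError(f"unknown mutation model kind {self.kind!r}")
        if not 0.0 <= self.rate <= 0.01:
            raise ValueError("mutation rate must be in [0, 0.01]")
        if not 0.0 <= self.p_multistep <= 1.0:
            raise ValueError("p_multistep must be in [0, 1]")
        if self.p_multistep > 0 and self.delta_g <= 2.0:
            raise ValueError(
                "mean multi-step size delta_g must exceed 2 repeat units "
                "(multi-step mutations move at least 2 units)"
            )
        if self.kind == "KAM" and self.n_states < 2:
            raise ValueError("KAM needs n_states >= 2")

    @property
    def geom_p(self) -> float:
        """Success parameter of the shifted-geometric multi-step size, so that
        1 + Geometric(geom_p) has mean delta_g."""
        return 1.0 / (self.delta_g - 1.0)

    @property
    def sigma2_g(self) -> float:
        """Implied variance of the multi-step size (shifted-geometric family)."""
        return (1.0 - self.geom_p) / self.geom_p**2


SMM = MutationModel(kind="SMM")
TPM_70 = MutationModel(kind="TPM", p_multistep=0.30, delta_g=3.1)
TPM_90 = MutationModel(kind="TPM", p_multistep=0.10, delta_g=3.1)
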