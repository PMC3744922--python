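"""Transgenic strain descriptions.

Each strain in the panel is described declaratively: which fluorophores it
carries (CFP donor, YFP acceptor), whether each is fused to human
alpha-synuclein, and whether the strain expresses alpha-synuclein at all
(fusions, or the free protein co-expressed with a marker).  These flags
drive both the plate-reader simulation and the expected-phenotype logic:
only a strain in which *both* fluorophores are tethered to alpha-synuclein
can bring donor and acceptor within Förster distance inside an aggregate
and produce sensitized emission.
"""

from __future__ import annotations

from dataclasses import dataclass


class StrainError(ValueError):
    """Raised for an inconsistent strain description or an unknown strain."""


@dataclass(frozen=True)
class StrainSpec:
    """Declarative genotype of a transgenic line.

    Parameters
    ----------
    name:
        Short label, e.g. ``"N2"``, ``"C"``, ``"SV"``, ``"SC+SV"``.
    has_donor:
        CFP (Cerulean) is expressed.
    has_acceptor:
        YFP (Venus) is expressed.
    donor_fused_to_syn:
        The CFP moiety is a C-terminal alpha-synuclein fusion (SC).
    acceptor_fused_to_syn:
        The YFP moiety is an alpha-synuclein fusion (SV).
    expresses_syn:
        The strain expresses alpha-synuclein in any form — as a fusion or
        as the free protein co-injected with a marker (S+V).
    """

    name: str
    has_donor: bool = False
    has_acceptor: bool = False
    donor_fused_to_syn: bool = False
    acceptor_fused_to_syn: bool = False
    expresses_syn: bool = False

    def __post_init__(self) -> None:
        if self.donor_fused_to_syn and not self.has_donor:
            raise StrainError(
                f"{self.name}: donor_fused_to_syn requires has_donor"
            )
        if self.acceptor_fused_to_syn and not self.has_acceptor:
            raise StrainError(
                f"{self.name}: acceptor_fused_to_syn requires has_acceptor"
            )
        if (self.donor_fused_to_syn or self.acceptor_fused_to_syn) and not self.expresses_syn:
            raise StrainError(
                f"{self.name}: a synuclein fusion implies expresses_syn"
            )

    @property
    def fret_competent(self) -> bool:
        """True when aggregation can generate sensitized emission.

        Both fluorophores must be tethered to alpha-synuclein so that
        co-aggregation brings donor and acceptor into FRET range; a free
        fluorophore stays diffuse in the cytosol.
        """
        return self.donor_fused_to_syn and self.acceptor_fused_to_syn

    @property
    def has_marker(self) -> bool:
        """True when the strain carries at least one fluorescent protein."""
        return self.has_donor or self.has_acceptor


def default_panel() -> dict[str, StrainSpec]:
    """The study's strain panel, keyed by strain label.

    N2 wild type; free-fluorophore controls C, V, CV (tandem CFP::YFP
    fusion) and C+V (co-expressed); alpha-synuclein lines S+V (free
    synuclein plus free YFP), the single fusions SC and SV, and the
    doubly transgenic SC+SV used for the aggregation FRET assay.
    """
    return {
        s.name: s
        for s in (
            StrainSpec("N2"),
            StrainSpec("C", has_donor=True),
            StrainSpec("V", has_acceptor=True),
            StrainSpec("CV", has_donor=True, has_acceptor=True),
            StrainSpec("C+V", has_donor=True, has_acceptor=True),
            StrainSpec("S+V", has_acceptor=True, expresses_syn=True),
            StrainSpec(
                "SC",
                has_donor=True,
                donor_fused_to_syn=True,
                expresses_syn=True,
            ),
            StrainSpec(
                "SV",
                has_acceptor=True,
                acceptor_fused_to_syn=True,
                expresses_syn=True,
            ),
            StrainSpec(
                "SC+SV",
                has_donor=True,
                has_acceptor=True,
                donor_fused_to_syn=True,
                acceptor_fused_to_syn=True,
                expresses_syn=True,
            ),
        )
    }
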