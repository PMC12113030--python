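"""Blocked polyalanine peptide descriptions.

A blocked (ALA)n peptide — acetyl N-cap, amide C-cap — supports n - 2
α-helical i -> i+4 hydrogen bonds: the first donor C=O is the acetyl cap
(paired with the backbone N-H of residue 4) and the last is residue n - 3
(paired with the C-terminal amide N-H₂).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class InvalidPeptideError(ValueError):
    """Peptide too short to form any helical hydrogen bond."""


@dataclass(frozen=True)
class PeptideSpec:
    """A blocked alanine peptide Ac-(Ala)n-NH2.

    Parameters
    ----------
    n_residues : int
        Number of alanine residues (n >= 3).
    blocked : bool
        Whether the termini carry acetyl/amide blocking groups. Only the
        blocked topology is supported; the flag exists to make the
        assumption explicit.
    """

    n_residues: int
    blocked: bool = True
    maxhb: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.blocked:
            raise InvalidPeptideError("only blocked (capped) peptides are supported")
        if self.n_residues < 3:
            raise InvalidPeptideError(
                f"a blocked (ALA)n peptide needs n >= 3 residues to form a "
                f"helical hydrogen bond, got n={self.n_residues}"
            )
        object.__setattr__(self, "maxhb", self.n_residues - 2)

    def bond_labels(self) -> list[str]:
        """Donor->acceptor labels for the maxhb candidate bonds, N to C.

        Bond k pairs the C=O of residue k (0 = acetyl cap) with the N-H
        of residue k + 4 (n + 1 = C-terminal amide cap).
        """
        labels = []
        for k in range(self.maxhb):
            donor = "Ace" if k == 0 else f"Ala{k}"
            acc_idx = k + 4
            acceptor = "Nme" if acc_idx > self.n_residues else f"Ala{acc_idx}"
            labels.append(f"{donor}:O-{acceptor}:N")
        return labels


def maxhb_for_peptide(spec: PeptideSpec) -> int:
    """Maximum number of helical hydrogen bonds for a blocked peptide."""
    return spec.maxhb
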