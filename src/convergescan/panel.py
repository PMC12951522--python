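"""Sample panel: which diploid individual belongs to which species and morphotype.

The panel defines the two independent slender–stout species pairings that the
convergence score contrasts. Morphotype labels are restricted to ``slender``
and ``stout``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

VALID_MORPHS = ("slender", "stout")


@dataclass(frozen=True)
class Pairing:
    """Two ordered slender–stout species pairs used by the convergence score."""

    slender_a: str
    stout_a: str
    slender_b: str
    stout_b: str

    def species(self) -> tuple[str, str, str, str]:
        return (self.slender_a, self.stout_a, self.slender_b, self.stout_b)

    def __post_init__(self) -> None:
        if len(set(self.species())) != 4:
            raise ValueError("the four pairing species must be distinct")


@dataclass
class SpeciesPanel:
    """Sample → species → morphotype map.

    Parameters
    ----------
    samples
        Ordered sample IDs (the genotype-matrix column order).
    species_of
        Mapping from sample ID to species label.
    morph_of
        Mapping from species label to morphotype ("slender" or "stout").
    pairing
        The two slender–stout species pairs contrasted by the convergence
        score. Inferred when exactly two species carry each morphotype among
        four species; otherwise must be given.
    """

    samples: list[str]
    species_of: dict[str, str]
    morph_of: dict[str, str]
    pairing: Pairing | None = None
    _members: dict[str, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            dupes = {s for s in self.samples if self.samples.count(s) > 1}
            raise ValueError(f"duplicate sample IDs: {sorted(dupes)}")
        missing = [s for s in self.samples if s not in self.species_of]

        if missing:
            raise ValueError(f"samples without species assignment: {missing}")
        for sp, morph in self.morph_of.items():
            if morph not in VALID_MORPHS:
                raise ValueError(
                    f"species {sp!r}: morphotype {morph!r} not in {VALID_MORPHS}"
                )
        for sp in self.species():
            if sp not in self.morph_of:
                raise ValueError(f"species {sp!r} has no morphotype label")
        if self.pairing is None:
            try:
                self.pairing = self._infer_pairing()
            except ValueError:
                self.pairing = None  # resolved lazily via require_pairing()
        if self.pairing is not None:
            for sp in self.pairing.species():
                if sp not in self.species():
                    raise ValueError(f"pairing species {sp!r} absent from panel")
        self._members = {sp: [] for sp in self.species()}
        for i, s in enumerate(self.samples):
            self._members[self.species_of[s]].append(i)
        empty = [sp for sp, idx in self._members.items() if not idx]
        if empty:
            raise ValueError(f"species with no samples: {empty}")

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.species_of[s], None)
        return list(seen)

    def require_pairing(self) -> Pairing:
        """The configured/inferred pairing, or an informative error."""
        if self.pairing is None:
            raise ValueError(
                "no slender-stout pairing configured and none inferable "
                "(need exactly 2 slender and 2 stout species); pass one "
                "explicitly"
            )
        return self.pairing

    def sample_indices(self, species: str) -> list[int]:
        """Column indices of a species' samples in the genotype matrix."""
        return self._members[species]

    def morph_members(self, morph: str) -> list[int]:
        """Column indices of every sample whose species has this morphotype."""
        return [
            i
            for i, s in enumerate(self.samples)
            if self.morph_of[self.species_of[s]] == morph
        ]

    def _infer_pairing(self) -> Pairing:
        slender = [sp for sp in self.species() if self.morph_of[sp] == "slender"]
        stout = [sp for sp in self.species() if self.morph_of[sp] == "stout"]
        if len(slender) == 2 and len(stout) == 2:
            return Pairing(slender[0], stout[0], slender[1], stout[1])
        raise ValueError(
            "pairing cannot be inferred (need exactly 2 slender and 2 stout "
            "species); pass it explicitly"
        )


def load_panel(path, pairing: Pairing | None = None) -> SpeciesPanel:
    """Load a sample panel from a TSV with columns sample, species, morphotype.

    A header row is required. Raises on duplicate samples, unknown morphotype
    labels, or a pairing species missing from the panel.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "species", "morphotype"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel TSV must have columns {sorted(required)}")
    samples = df["sample"].tolist()
    species_of = dict(zip(df["sample"], df["species"]))
    morph_of: dict[str, str] = {}
    for sp, m in zip(df["species"], df["morphotype"]):
        if sp in morph_of and morph_of[sp] != m:
            raise ValueError(f"species {sp!r} assigned conflicting morphotypes")
        morph_of[sp] = m
    return SpeciesPanel(samples, species_of, morph_of, pairing)
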