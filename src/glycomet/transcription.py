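"""TPM conversion and relative-transcription metrics.

Mapped transcript counts are converted to transcripts per million (TPM):
per-gene count/length rates rescaled so the rates of a designated
normalization universe sum to one million. MAG-level gene TPMs use the
whole-community universe as denominator so that MAG and community values
are commensurable.

The MAG relative-transcription metric is the quotient of the mean TPM of
a MAG's single-copy ribosomal proteins and the sample-wide mean over the
same 16 markers — the proportional transcription of that genome relative
to the community average.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

__all__ = [
    "tpm",
    "mag_tpm",
    "mag_relative_transcription",
    "family_transcription_share",
    "up_transcribed_families",
    "OTHER_COMMUNITY",
]

OTHER_COMMUNITY = "other community members"


def tpm(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    universe: Iterable[str] | None = None,
) -> dict[str, float]:
    """Transcripts per million with an explicit normalization universe.

    rate_g = count_g / length_g; tpm_g = 1e6 * rate_g / sum of universe
    rates. Genes outside the universe still receive TPM values computed
    against the universe denominator. An all-zero universe yields all-zero
    TPM with a warning.
    """
    universe = set(universe) if universe is not None else set(counts)
    denom = 0.0
    for g in universe:
        if lengths[g] <= 0:
            raise ValueError(f"gene {g} has non-positive length")
        denom += counts.get(g, 0) / lengths[g]
    if denom == 0:
        warnings.warn("all universe counts are zero; TPM set to 0", stacklevel=2)
        return {g: 0.0 for g in counts}
    out = {}
    for g, c in counts.items():
        if lengths[g] <= 0:
            raise ValueError(f"gene {g} has non-positive length")
        out[g] = 1e6 * (c / lengths[g]) / denom
    return out


def mag_tpm(
    mag_counts: Mapping[str, int],
    lengths: Mapping[str, int],
    community_counts: Mapping[str, int],
) -> dict[str, float]:
    """TPM of MAG genes against the COMMUNITY denominator.

    The denominator sums rates over all community genes, so MAG TPMs are
    on the same scale as community TPMs and their total is bounded by 1e6.
    """
    all_counts = dict(community_counts)
    all_counts.update(mag_counts)
    full = tpm(all_counts, lengths, universe=set(community_counts))
    return {g: full[g] for g in mag_counts}


def mag_relative_transcription(
    mag_scrbp_tpms: Mapping[str, float],
    sample_scrbp_tpms: Mapping[str, float],
    min_markers: int = 8,
) -> float:
    """mean(MAG SC-RBP TPMs) / mean(sample SC-RBP TPMs).

    The MAG mean is taken over the markers the MAG possesses; fewer than
    ``min_markers`` present markers make the estimate unreliable and raise.
    """
    if len(mag_scrbp_tpms) < min_markers:
        raise ValueError(
            f"MAG carries {len(mag_scrbp_tpms)} SC-RBP markers; "
            f"at least {min_markers} required for a relative-transcription value"
        )
    if not sample_scrbp_tpms:
        raise ValueError("sample SC-RBP TPMs are empty")
    sample_mean = sum(sample_scrbp_tpms.values()) / len(sample_scrbp_tpms)
    if sample_mean <= 0:
        raise ValueError("sample mean SC-RBP TPM is zero; ratio undefined")
    mag_mean = sum(mag_scrbp_tpms.values()) / len(mag_scrbp_tpms)
    return mag_mean / sample_mean


def family_transcription_share(
    community_family_transcripts: float,
    per_mag_family_transcripts: Mapping[str, float],
) -> dict[str, float] | None:
    """Per-MAG share of one CAZyme family's community transcription.

    share_m = transcripts_m / community total; the unassigned remainder is
    reported under :data:`OTHER_COMMUNITY`. Returns None when the family
    has no community transcripts (absent family).
    """
    if community_family_transcripts == 0:
        return None
    total_mag = sum(per_mag_family_transcripts.values())
    if total_mag > community_family_transcripts + 1e-9:
        raise ValueError(
            "per-MAG transcripts exceed the community total for this family"
        )
    shares = {
        m: v / community_family_transcripts
        for m, v in per_mag_family_transcripts.items()
    }
    shares[OTHER_COMMUNITY] = max(
        0.0, 1.0 - total_mag / community_family_transcripts
    )
    return shares


def up_transcribed_families(
    mag_family_tpms: Mapping[str, float], mag_scrbp_mean_tpm: float
) -> set[str]:
    """Families whose summed TPM strictly exceeds the MAG's mean SC-RBP
    TPM — transcribed above the ribosomal-protein baseline."""
    return {f for f, v in mag_family_tpms.items() if v > mag_scrbp_mean_tpm}
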