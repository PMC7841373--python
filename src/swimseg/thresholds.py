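"""Detector thresholds and window parameters with their published defaults.

Every threshold used by the macro and micro detectors lives here so a whole
analysis can be re-parameterized (or sensitivity-swept) from one object.
Acceleration thresholds are in g, angular-velocity thresholds in °/s,
instantaneous-energy thresholds in (°/s)², durations in seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields

from .errors import InvalidParameterError

__all__ = ["ThresholdSet"]


@dataclass
class ThresholdSet:
    # -- common filtering -------------------------------------------------
    filter_fc: float = 10.0      # Hz, noise-removal low-pass (2nd-order Butterworth)
    filter_order: int = 2

    # -- swimming bout detection ------------------------------------------
    fraction_B: float = 0.3      # sharp-change fraction of the max filtered derivative
    bout_fc: float = 0.15        # Hz, posture-level-shift low-pass for bout detection
    TH_BW: float = 1.6           # g, wrist |Acc| envelope threshold
    bout_envelope_window: float = 1.0   # s, envelope smoothing window
    bout_merge_gap: float = 10.0        # s, wrist sub-intervals closer than this merge
    min_bout_duration: float = 5.0      # s, shorter intervals are discarded

    # -- lap (approximate turn) detection ---------------------------------
    min_lap_time: float = 10.0   # s, minimum separation between turns
    turn_peak_fraction: float = 0.6     # accepted peaks exceed this fraction of bout max
    turn_min_amp: float = 1.2    # g, absolute floor (above bout median) for turn peaks
    TH_LW: float = 200.0         # °/s, wrist |Gyr| drop threshold during turn
    rs_turn_ref_window: float = 2.0     # s, shank reference window for TH_LS
    rw_turn_min_drop: float = 0.4       # s, minimal duration of a wrist |Gyr| drop
    rw_turn_max_drop: float = 8.0       # s, maximal duration of a wrist |Gyr| drop

    # -- swimming technique identification --------------------------------
    technique_window: float = 6.0       # s, centered at the lap midpoint
    TH_StyleSA: float = 0.16     # g, sacrum Acc_x spectral-peak threshold (butterfly)
    TH_StyleHE: float = 0.2      # g, head |Acc_x,y| spectral-peak threshold (butterfly)
    TH_StyleWmean: float = 1.7   # g, wrist mean |Acc| threshold (butterfly)
    TH_StyleWvar: float = 0.01   # g², wrist smoothed-|Acc| variance threshold (front crawl)
    style_fmin: float = 0.3      # Hz, arm-stroke band for the spectral-peak feature
    style_fmax: float = 1.5      # Hz, upper edge of the arm-stroke band
    rw_var_smooth: float = 0.8333       # s, |Acc| smoothing before the variance feature
    rs_roll_ratio: float = 0.05  # shank var(Gyr_y)/var(Gyr_z) split, front crawl vs butterfly
    pca_dominance: float = 0.5   # |PC1 · axis| above this claims the axis

    # -- beginning of wall push-off ---------------------------------------
    push_search_pre: float = 1.0        # s before the macro anchor
    push_search_post: float = 2.0       # s after the macro anchor
    push_min_peak: float = 0.3   # g (SA/HE Acc_y or |Acc| peak floor)
    push_rs_gyr: float = 150.0   # °/s, shank |Gyr| push peak floor
    push_detrend_fc: float = 0.5 # Hz, posture-trend removal for push detection

    # -- beginning of glide ------------------------------------------------
    glide_search: float = 3.0    # s after Push_B
    glide_trough_th: float = -0.1       # g, SA/HE Acc_y trough threshold
    glide_rs_gyr: float = 80.0   # °/s, shank |Gyr| secondary-peak floor
    glide_rw_peak: float = -0.5  # g, wrist Acc_y peak threshold (signal near zero)
    glide_rw_prom: float = 0.15  # g, wrist glide-peak prominence (rejects noise)
    glide_min_after_push: float = 0.1   # s, skip the push extremum itself

    # -- beginning of strokes preparation ----------------------------------
    stpr_search: float = 8.0     # s after Glid_B
    TH_SPSA: float = 1.0         # g, sacrum |Acc_x| peak magnitude
    TH_SPSAvar: float = 0.06     # g², sacrum local Acc_x variance gate
    spsa_var_window: float = 0.5        # s, window for the local variance gate
    TH_SPHE: float = -0.5        # g, head Acc_y trough threshold
    TH_SPHEprom: float = 0.1     # g, head trough prominence
    TH_SPRW: float = -0.9        # g, wrist trough threshold on |Acc| − 1 g
    TH_SPRS: float = 1.3         # g, shank |Acc_x| kick-peak threshold
    stpr_bas_rs: float = 0.25    # g, shank Acc_y positive-peak floor (backstroke)

    # -- beginning of swimming ---------------------------------------------
    swim_search: float = 10.0    # s after StPr_B
    TH_SSA_FCBaS: float = 200.0  # °/s, sacrum |Gyr_y| roll threshold
    TH_SSA_BrS: float = 550.0    # (°/s)², sacrum IMF2 Gyr_z energy threshold
    TH_SSA_BF: float = 0.1       # g, sacrum IMF2 Acc_y peak threshold
    TH_SHE_FC: float = 5000.0    # (°/s)², head Gyr_y energy threshold
    TH_SHE_BFBrS: float = 12000.0       # (°/s)², head Gyr_z energy threshold
    TH_SHE_BaS: float = 1000.0   # (°/s)², head Gyr_z energy drop threshold
    TH_T_RS: float = 1.7         # g, shank IMF2 peak threshold
    emd_fc: float = 3.0          # Hz, low-pass before empirical mode decomposition
                                 # (keeps kicks as mode 1, stroke-rate as mode 2)
    swim_wrist_peak_fraction: float = 0.5      # first wrist peak: fraction of window max

    # -- beginning of turn --------------------------------------------------
    turn_search_pre: float = 3.0        # s before the approximate turn
    turn_search_post: float = 1.0       # s after the approximate turn
    turn_min_peak_fraction: float = 0.4 # qualifying peak: fraction of window max

    def validate(self) -> "ThresholdSet":
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not abs(float(v)) < 1e12:
                raise InvalidParameterError(f"threshold {f.name} must be finite")
        return self

    def replace(self, **kwargs) -> "ThresholdSet":
        return dataclasses.replace(self, **kwargs).validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown threshold names: {sorted(unknown)}")
        return cls(**d).validate()
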