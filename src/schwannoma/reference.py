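"""Reference rule base distributed with the package.

These constants transcribe the published clinical reference results the
package's decision-support rules are built around: the five per-ranker top-10
variable lists for the static (CBR) and longitudinal (PDA) analyses, and the
expert shortlists derived from them.  They serve as fixed inputs to the
consensus arithmetic and as the feature sets behind the reference decision
trees in :mod:`schwannoma.trees`; the occurrence counts and average ranks are
always recomputed from these lists, never stored.
"""

from __future__ import annotations

from .consensus import RankedList

#: Per-ranker top-10 variable lists for the static per-checkup (CBR) analysis.
CBR_RANKINGS: tuple[RankedList, ...] = (
    RankedList("decision_tree", (
        "PTA_VS_SR8", "Koos", "PTA_D_AR4", "SRT", "PTA_H_SR8",
        "PTA_VS_SR4", "PTA_D_AR8", "PTA_H_IR8", "PTA_VS_3", "Size",
    )),
    RankedList("random_forest", (
        "Koos", "PTA_VS_SR8", "SRT", "PTA_VS_AR4", "PTA_VS_3",
        "PTA_H_SR8", "PTA_VS_SR4", "PTA_VS_0.25", "MDL", "PTA_H_8",
    )),
    RankedList("gradient_boosting", (
        "Koos", "PTA_VS_SR8", "PTA_H_SR8", "SRT", "Size",
        "PTA_VS_IR8", "PTA_D_AR4", "PTA_D_AR8", "PTA_H_IR8", "PTA_VS_1",
    )),
    RankedList("logistic_regression", (
        "Koos", "Size", "SRT", "PTA_VS_0.25", "PTA_H_8",
        "PTA_H_0.5", "PTA_H_2", "PTA_VS_6", "PTA_VS_8", "SDS",
    )),
    RankedList("lasso", (
        "Koos", "PTA_H_SR8", "Size", "PTA_VS_SR4", "SRT",
        "PTA_H_IR8", "SDS", "PTA_VS_SR8", "PTA_VS_0.25", "MDR",
    )),
)

#: Per-ranker top-10 lists for the longitudinal per-patient (PDA) analysis.
#: The logistic-regression list has nine entries: its printed seventh entry
#: duplicates the sixth and is dropped (duplicates are not representable).
PDA_RANKINGS: tuple[RankedList, ...] = (
    RankedList("decision_tree", (
        "Size_LD", "Koos_LD", "Size_AC", "PTA_VS_AR4_AC", "Koos_TD",
        "PTA_VS_AR8_AC", "PTA_D_AR8_IC", "PTA_D_AR4_SC", "SRT_AC", "Size_SC",
    )),
    RankedList("random_forest", (
        "Size_LD", "Koos_LD", "Size_SC", "SRT_LD", "Koos_TD",
        "PTA_VS_AR8_IC", "PTA_D_AR4_SC", "PTA_D_AR4_LD", "PTA_D_AR8_AC", "PTA_VS_AR4_SC",
    )),
    RankedList("gradient_boosting", (
        "Koos_LD", "Size_SC", "Size_LD", "PTA_VS_AR4_SC", "SRT_SC",
        "PTA_VS_AR8_SC", "PTA_VS_AR4_LD", "PTA_D_AR8_SC", "PTA_D_AR8_LD", "Size_AC",
    )),
    RankedList("logistic_regression", (
        "Size_LD", "PTA_VS_AR4_SC", "Size_SC", "Koos_LD", "PTA_D_AR8_SC",
        "PTA_VS_AR8_SC", "PTA_D_AR4_SC", "PTA_D_AR8_IC", "Koos_TD",
    ), ranks=(1, 2, 3, 4, 5, 6, 8, 9, 10)),
    RankedList("lasso", (
        "Koos_LD", "PTA_D_AR4_IC", "SRT_IC", "SRT_LD", "PTA_VS_AR8_IC",
        "PTA_D_AR8_LD", "PTA_D_AR8_IC", "PTA_VS_AR4_IC", "Size_AC", "PTA_VS_AR4_AC",
    )),
)

#: Expert shortlist after the consensus rule plus judgment (CBR, initial).
CBR_EXPERT_INITIAL: tuple[str, ...] = (
    "Koos", "SRT", "PTA_VS_SR8", "PTA_H_SR8", "Size",
    "PTA_VS_SR4", "PTA_VS_0.25", "PTA_H_IR8", "PTA_D_AR4",
)
#: Final minimal expert variable set for the static analysis.
CBR_EXPERT_FINAL: tuple[str, ...] = (
    "Koos", "SRT", "PTA_VS_SR8", "PTA_H_SR8", "PTA_D_AR4",
)

#: Expert shortlist (PDA, initial) and final minimal set.
PDA_EXPERT_INITIAL: tuple[str, ...] = (
    "Koos_LD", "Size_LD", "Size_SC", "Koos_TD",
    "PTA_D_AR4_SC", "PTA_VS_AR4_SC", "PTA_D_AR8_IC", "Size_AC",
)
PDA_EXPERT_FINAL: tuple[str, ...] = (
    "Koos_LD", "Size_SC", "PTA_D_AR4_SC", "PTA_VS_AR4_SC",
)


def cbr_reference_rankings() -> list[RankedList]:
    return list(CBR_RANKINGS)


def pda_reference_rankings() -> list[RankedList]:
    return list(PDA_RANKINGS)
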