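"""Published reference data for the two docetaxel-resistance cell-line models.

The MCF-7 and MDA-MB-231 stepwise-selection experiments exposed cells to
gradually increasing docetaxel doses; a handful of sub-lines along each
timeline (plus parental and final resistant populations) were chosen for
exome analysis.  This module packages those timelines — every concentration
step with passage numbers and, where measured, doubling times — together
with the published consequence tallies of acquired-and-selected variants in
the earliest analysed sub-lines (0.27 nM), which serve as worked examples
for the tally machinery.
"""

from __future__ import annotations

from .stage_io import Stage, StageSeries

# Full dose escalation schedules: (dose nM, passages, analysed sub-line label
# or None, doubling time days or None).  Doses below 1 nM are the pM steps.
MCF7_DOSE_SCHEDULE = [
    (0.0, None, "MCF-7_PAR", 1.3),
    (0.01, (1, 3), None, None),
    (0.03, (4, 6), None, None),
    (0.09, (7, 9), None, None),
    (0.27, (10, 12), "MCF-7_SUB-0.27nM", 1.98),
    (0.81, (13, 15), None, None),
    (1.2, (16, 18), "MCF-7_SUB-1.2nM", 1.8),
    (1.8, (19, 21), None, None),
    (2.25, (22, 24), None, None),
    (2.8, (25, 27), None, None),
    (3.5, (28, 30), None, None),
    (5.0, (31, 33), None, None),
    (7.5, (34, 36), "MCF-7_SUB-7.5nM", 1.91),
    (15.0, (37, 39), None, None),
    (30.0, (40, 42), None, None),
    (45.0, (43, 45), "MCF-7_SUB-45nM", 1.8),
    (55.0, (46, 48), None, None),
    (65.0, (49, 49), "MCF-7_RES-65nM", 1.4),
]

MDA_DOSE_SCHEDULE = [
    (0.0, None, "MDA_PAR", 1.1),
    (0.01, (1, 3), None, None),
    (0.03, (4, 6), None, None),
    (0.09, (7, 9), None, None),
    (0.27, (10, 12), "MDA_SUB-0.27nM", 1.48),
    (0.81, (13, 15), None, None),
    (1.2, (16, 18), None, None),
    (1.8, (19, 21), None, None),
    (2.25, (22, 24), None, None),
    (2.8, (25, 27), None, None),
    (3.5, (28, 30), None, None),
    (5.0, (31, 33), "MDA_SUB-5nM", 1.6),
    (15.0, (34, 36), "MDA_SUB-15nM", 2.8),
    (45.0, (37, 39), None, None),
    (60.0, (40, 42), None, None),
    (80.0, (43, 45), None, None),
    (100.0, (46, 48), "MDA_SUB-100nM", 1.0),
    (120.0, (49, 51), None, None),
    (150.0, (52, 52), "MDA_RES.150nM", 1.0),
]


def concentration_steps(schedule) -> int:
    """Number of non-zero docetaxel concentration steps applied to the cells."""
    return sum(1 for dose, *_ in schedule if dose > 0)


def _series_from_schedule(schedule) -> StageSeries:
    analysed = [row for row in schedule if row[2] is not None]
    stages = []
    for i, (dose, passages, label, dt) in enumerate(analysed):
        role = "parental" if i == 0 else ("final" if i == len(analysed) - 1 else "intermediate")
        stages.append(
            Stage(
                label=label,
                docetaxel_nM=dose,
                role=role,
                passage_range=passages,
                doubling_time_days=dt,
            )
        )
    return StageSeries(stages=tuple(stages))


def mcf7_series() -> StageSeries:
    """The six analysed MCF-7 populations: parental, four sub-lines, final resistant."""
    return _series_from_schedule(MCF7_DOSE_SCHEDULE)


def mda_series() -> StageSeries:
    """The six analysed MDA-MB-231 populations."""
    return _series_from_schedule(MDA_DOSE_SCHEDULE)


# Published per-consequence counts of acquired-and-selected variant
# annotations in the earliest analysed sub-line (0.27 nM) of each model.
# Counts are per variant-transcript annotation, hence exceed variant counts.
MCF7_027NM_CONSEQUENCE_COUNTS = {
    "3_prime_UTR_variant": 26,
    "5_prime_UTR_variant": 6,
    "NMD_transcript_variant": 70,
    "TF_binding_site_variant": 0,
    "downstream_gene_variant": 169,
    "feature_elongation": 29,
    "feature_truncation": 63,
    "frameshift_variant": 0,
    "inframe_insertion": 0,
    "intron_variant": 618,
    "mature_miRNA_variant": 0,
    "missense_variant": 44,
    "nc_transcript_variant": 182,
    "non_coding_exon_variant": 45,
    "regulatory_region_variant": 27,
    "splice_acceptor_variant": 0,
    "splice_region_variant": 12,
    "stop_gained": 0,
    "synonymous_variant": 35,
    "upstream_gene_variant": 95,
}

MDA_027NM_CONSEQUENCE_COUNTS = {
    "3_prime_UTR_variant": 25,
    "5_prime_UTR_variant": 6,
    "NMD_transcript_variant": 68,
    "TF_binding_site_variant": 1,
    "downstream_gene_variant": 197,
    "feature_elongation": 47,
    "feature_truncation": 59,
    "frameshift_variant": 0,
    "inframe_insertion": 1,
    "intron_variant": 741,
    "mature_miRNA_variant": 0,
    "missense_variant": 18,
    "nc_transcript_variant": 202,
    "non_coding_exon_variant": 57,
    "regulatory_region_variant": 32,
    "splice_acceptor_variant": 0,
    "splice_region_variant": 22,
    "stop_gained": 0,
    "synonymous_variant": 60,
    "upstream_gene_variant": 169,
}
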