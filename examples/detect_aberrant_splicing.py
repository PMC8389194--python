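"""Carrier-versus-controls comparison on a synthetic NBN splice-site
carrier.

Builds junction counts for a carrier in whom exon-5 skipping consumes ~30%
of junction reads (the signature of a donor-site variant that abolishes
normal splicing of the exon) and six controls where the same event sits at
its natural ~0.8% level, then grades the carrier's events.  The report
columns show both quantification conventions side by side:
junction-percentage p = alt/canonical and aberrant fraction
f = alt/(alt+canonical) = 100p/(100+p).
"""

from splicecat import (JunctionRecord, compare_carrier_controls,
                       merge_samples, render_report)
from splicecat.events import junction_records_from_consequence
from splicecat.fixtures import load_fixture

model = load_fixture("nbn_model")
DEPTH = 100_000


def sample(events):
    recs = [JunctionRecord(model.chrom, *model.intron_genomic(i), 2,
                           annotated_flag=1, unique_reads=DEPTH)
            for i in range(1, model.n_introns + 1)]
    for consequence, reads in events:
        recs += junction_records_from_consequence(model, consequence, reads=reads)
    return recs


carrier = sample([("r.481_584del", 30_000)])        # exon-5 skip at ~30%
controls = merge_samples({f"C{i}": sample([("r.481_584del", 800)])
                          for i in range(1, 7)})     # natural level ~0.8%

calls = compare_carrier_controls(model, carrier, controls)
print(render_report(calls))
call = calls[0]
print(f"{call.event.name} is graded '{call.impact_class}': the carrier "
      f"expresses it at {call.carrier_percentage:.1f}% of canonical reads "
      f"(aberrant fraction {call.carrier_fraction:.1f}%) against a control "
      f"maximum of {call.control_max_percentage:.1f}%.")
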