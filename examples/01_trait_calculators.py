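"""Compute the six growth traits from one raw performance-test record.

Builds a single male record (160 test days, 110 kg at test, 12 mm backfat,
65 -> 110 kg over the test, 2.5 kg feed/day) and prints each derived trait.
"""

from sociogwas import (
    GrowthRecord,
    adg_and_fcr,
    average_metabolic_weight,
    backfat_at_100kg,
    days_to_100kg,
    residual_feed_intake,
)

rec = GrowthRecord(
    animal_id="pig001", sex="male", test_days=160, test_weight=110.0,
    test_bft=12.0, bw_start=65.0, bw_end=110.0, adfi=2.5,
)

adg, fcr = adg_and_fcr(rec)
rec.adg = adg
print(f"ADG  = {adg:8.4f} kg/day   (weight gain per test day)")
print(f"FCR  = {fcr:8.4f}          (feed per kg of gain)")
print(f"D100 = {days_to_100kg(rec):8.3f} days     (age standardised to 100 kg)")
print(f"B100 = {backfat_at_100kg(rec):8.4f} mm       (backfat standardised to 100 kg)")
amw = average_metabolic_weight(rec)
print(f"AMW  = {amw:8.4f} kg^0.6   (mean metabolic weight over the test)")
print(f"RFI  = {residual_feed_intake(rec):8.2f} g/day    "
      "(feed intake not explained by growth, backfat, maintenance)")
print("\nA negative RFI marks an animal eating less than its growth and "
      "maintenance predict, i.e. a feed-efficient animal.")
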