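# Uninformative adverse-event terms dropped before signal detection.
# One term per line; '#' starts a comment. Matching is case-insensitive
# after lowercasing and replacing spaces with underscores.
drug_ineffective
off_label_use
product_use_issue
drug_dose_omission
no_adverse_event
therapeutic_response_unexpected
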