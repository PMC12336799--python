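{instructions}

{language_rules}

{output_format_rules}

Examples:
{fewshot_examples}

List of standardized TG-263 structure names:
{tg263_names}

Input structure name: {input_name}
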