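You are reviewing one clinical note for a patient treated with one or more of the following immune checkpoint inhibitors: {ici_list}.
Using only the information in the note, answer every question below.

Clinical note:
<<<NOTE
{note_text}
NOTE>>>

{queries}

{output_instruction}
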